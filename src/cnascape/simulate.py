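"""Synthetic multi-platform cohorts with planted, recoverable structure.

The generator emulates the statistical skeleton of a copy-number-driven
tumor cohort: a genome of contiguous genes partitioned into segments;
per-sample segment-level gain/loss events (gains drawn as +0.5*U[1,2],
losses as -0.5*U[1,2], so magnitudes straddle the conventional +/-0.3
gain/loss thresholds); a latent phenotype P that is a weighted sum of the
mean CNA of designated driver segments plus noise; signature-gene
expression driven linearly by P; proportional-hazards survival tied to the
top-third phenotype group; subtype labels that can optionally confound both
the CNA event rate and the phenotype; and MAF-style mutation records.

Everything is deterministic given the config seed, and every emitted file
passes the package's own format validators.  The generator does not attempt
realistic allele frequencies, ploidy, purity, or real genome coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ClinicalTable,
    GeneCoords,
    MafTable,
    SegmentDefinitionTable,
    SegmentationTable,
    SignatureDefinition,
    write_clinical,
    write_expression_matrix,
    write_gene_coords,
    write_gmt,
    write_maf,
    write_seg,
    write_segment_definitions,
)

GENE_SPAN = 5_000  # bp per gene body
GENE_PITCH = 10_000  # bp between gene starts

#: Master seed of the reference design point used throughout the test suite.
REFERENCE_SEED = 20191211


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort (defaults = reference design point)."""

    seed: int = REFERENCE_SEED
    n_samples: int = 600
    n_genes: int = 2000
    n_chromosomes: int = 10
    n_segments: int = 40
    gain_prob: float = 0.3
    loss_prob: float = 0.3
    gene_noise_sd: float = 0.05
    driver_segments: tuple[int, ...] = (0,)
    driver_weights: tuple[float, ...] = (1.0,)
    phenotype_noise_sd: float = 0.25
    signature_size: int = 30
    signature_loading: float = 1.0
    expression_noise_sd: float = 1.0
    n_extra_signatures: int = 0
    n_subtypes: int = 1
    subtype_gain_shift: float = 0.0  # added to driver gain prob in subtype 0
    subtype_score_shift: float = 0.0  # added to P in subtype 0
    baseline_hazard: float = math.log(2) / 120.0  # per month; median ~120 months
    hazard_log_hr: float = math.log(2.0)  # high vs low phenotype group
    other_cause_hazard: float = 0.002
    admin_censor_months: float = 240.0
    n_mut_genes: int = 50
    mutation_rate: float = 0.05
    mutation_coupling: float = 0.0  # log-rate coupling to P
    cohort_name: str = "SYN"
    signature_genes: tuple[str, ...] | None = None  # fixed set (shared across cohorts)

    def validate(self) -> None:
        probs = [self.gain_prob, self.loss_prob, self.mutation_rate]
        if any(p < 0 or p > 1 for p in probs):
            raise ValidationError("event probabilities must lie in [0, 1]")
        if self.gain_prob + self.loss_prob + self.subtype_gain_shift > 1:
            raise ValidationError("gain + loss probability exceeds 1")
        if self.n_segments > self.n_genes:
            raise ValidationError("more segments than genes")
        if len(self.driver_segments) != len(self.driver_weights):
            raise ValidationError("driver_segments and driver_weights differ in length")
        if any(s < 0 or s >= self.n_segments for s in self.driver_segments):
            raise ValidationError("driver segment index out of range")
        if not all(np.isfinite(self.driver_weights)):
            raise ValidationError("driver weights must be finite")
        for sd in (self.gene_noise_sd, self.phenotype_noise_sd, self.expression_noise_sd):
            if sd < 0:
                raise ValidationError("noise standard deviations must be >= 0")


def confounded_config(seed: int = REFERENCE_SEED, **overrides) -> SimulationConfig:
    """Reference confounded scenario: subtype drives both CNA and phenotype.

    One subtype (ST1) has an elevated gain probability on the driver segment
    *and* a shifted signature mean, while the within-subtype CNA effect is
    zero (driver weight 0).  The unadjusted landscape should therefore call
    driver-segment genes and the subtype-adjusted landscape should not.
    """
    base = dict(
        seed=seed,
        driver_weights=(0.0,),
        n_subtypes=3,
        loss_prob=0.2,
        subtype_gain_shift=0.5,
        subtype_score_shift=1.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score recovery of every driver."""

    phenotype: pd.Series  # latent P per sample
    driver_segments: list[str]
    driver_signs: dict[str, int]
    subtypes: pd.Series
    signature_genes: list[str]
    phenotype_noise_sd: float
    hazard_log_hr: float


@dataclass
class SyntheticCohort:
    """One simulated cohort: every pipeline input plus the planted truth."""

    config: SimulationConfig
    seg: SegmentationTable
    coords: GeneCoords
    expression: pd.DataFrame
    clinical: ClinicalTable
    survival: pd.DataFrame  # sample-indexed: time, event, cause
    maf: MafTable
    signatures: list[SignatureDefinition]
    segment_defs: SegmentDefinitionTable
    gene_cna: pd.DataFrame
    truth: SyntheticTruth


def _partition(n_items: int, n_parts: int) -> list[int]:
    base = n_items // n_parts
    sizes = [base + (1 if i < n_items % n_parts else 0) for i in range(n_parts)]
    return sizes


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from ``config`` (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, G, K = config.n_samples, config.n_genes, config.n_segments

    samples = [f"{config.cohort_name}{i + 1:04d}" for i in range(n)]
    genes = [f"G{i + 1:05d}" for i in range(G)]
    seg_ids = [f"seg{k + 1:03d}" for k in range(K)]

    # --- genome: contiguous genes split over chromosomes, segments within chroms
    chrom_sizes = _partition(G, config.n_chromosomes)
    chrom_of_gene: list[str] = []
    local_idx: list[int] = []
    for c, size in enumerate(chrom_sizes):
        chrom_of_gene.extend([str(c + 1)] * size)
        local_idx.extend(range(size))
    starts0 = np.array(local_idx) * GENE_PITCH
    coords = GeneCoords(
        pd.DataFrame(
            {
                "gene": genes,
                "chrom": chrom_of_gene,
                "start": starts0,
                "end": starts0 + GENE_SPAN,
                "strand": "+",
            }
        )
    )

    # segments: contiguous gene blocks, never spanning a chromosome boundary
    seg_per_chrom = _partition(K, config.n_chromosomes)
    seg_of_gene = np.empty(G, dtype=int)
    members: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    gpos = 0
    k = 0
    for c, (csize, nseg) in enumerate(zip(chrom_sizes, seg_per_chrom)):
        block_sizes = _partition(csize, max(nseg, 1))
        for b in block_sizes:
            idx = list(range(gpos, gpos + b))
            seg_of_gene[idx] = k
            members[seg_ids[k]] = [genes[i] for i in idx]
            labels[seg_ids[k]] = f"{c + 1}b{len(members) - sum(seg_per_chrom[:c])}"
            gpos += b
            k += 1
    segment_defs = SegmentDefinitionTable(members=members, labels=labels)

    # --- subtypes
    subtypes = pd.Series(
        rng.integers(config.n_subtypes, size=n).astype(str), index=samples, name="subtype"
    ).map(lambda s: f"ST{int(s) + 1}")

    # --- segment-level CNA events
    u = rng.random((K, n))
    mag = 0.5 * rng.uniform(1.0, 2.0, size=(K, n))
    gain_p = np.full((K, n), config.gain_prob)
    if config.n_subtypes > 1 and config.subtype_gain_shift:
        confounded = (subtypes == "ST1").to_numpy()
        for d in config.driver_segments:
            gain_p[d, confounded] += config.subtype_gain_shift
    events = np.zeros((K, n))
    events[u < gain_p] = mag[u < gain_p]
    loss_mask = (u >= gain_p) & (u < gain_p + config.loss_prob)
    events[loss_mask] = -mag[loss_mask]

    # --- gene-level CNA = segment event + jitter
    gene_cna_values = events[seg_of_gene, :] + rng.normal(
        0.0, config.gene_noise_sd, size=(G, n)
    )
    gene_cna = pd.DataFrame(gene_cna_values, index=genes, columns=samples)

    # --- SEG emission (per-gene rows when jitter > 0, block rows otherwise)
    if config.gene_noise_sd > 0:
        seg_df = pd.DataFrame(
            {
                "sample": np.repeat(samples, G),
                "chrom": np.tile(np.asarray(chrom_of_gene), n),
                "start": np.tile(starts0, n),
                "end": np.tile(starts0 + GENE_SPAN, n),
                "value": gene_cna_values.T.ravel(),
            }
        )
    else:
        gene_index = {g: i for i, g in enumerate(genes)}
        block_start = np.array([starts0[gene_index[mem[0]]] for mem in members.values()])
        block_end = np.array(
            [starts0[gene_index[mem[-1]]] + GENE_SPAN for mem in members.values()]
        )
        block_chrom = np.array([chrom_of_gene[gene_index[mem[0]]] for mem in members.values()])
        seg_df = pd.DataFrame(
            {
                "sample": np.repeat(samples, K),
                "chrom": np.tile(block_chrom, n),
                "start": np.tile(block_start, n),
                "end": np.tile(block_end, n),
                "value": events.T.ravel(),
            }
        )
    seg_table = SegmentationTable(seg_df)

    # --- latent phenotype
    seg_means = np.vstack(
        [gene_cna_values[seg_of_gene == k_].mean(axis=0) for k_ in range(K)]
    )
    eps = rng.normal(0.0, config.phenotype_noise_sd, size=n)
    P = eps.copy()
    for d, w in zip(config.driver_segments, config.driver_weights):
        P += w * seg_means[d]
    if config.n_subtypes > 1 and config.subtype_score_shift:
        P += config.subtype_score_shift * (subtypes == "ST1").to_numpy()
    phenotype = pd.Series(P, index=samples, name="phenotype")

    # --- expression: signature genes track P; background genes are noise
    if config.signature_genes is not None:
        sig_genes = list(config.signature_genes)
        unknown = sorted(set(sig_genes) - set(genes))
        if unknown:
            raise ValidationError(f"signature gene(s) {unknown[:5]} not in the genome")
    else:
        non_driver = [g for g, s in zip(genes, seg_of_gene) if s not in config.driver_segments]
        sig_genes = sorted(rng.choice(non_driver, size=config.signature_size, replace=False))
    expr = rng.normal(0.0, 1.0, size=(G, n))
    sig_rows = [genes.index(g) for g in sig_genes]
    expr[sig_rows, :] = config.signature_loading * P + rng.normal(
        0.0, config.expression_noise_sd, size=(len(sig_rows), n)
    )
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    signatures = [
        SignatureDefinition(name="sig_main", description="planted phenotype", genes=sig_genes)
    ]
    for e in range(config.n_extra_signatures):
        extra = sorted(rng.choice(genes, size=20, replace=False))
        signatures.append(
            SignatureDefinition(name=f"sig_extra{e + 1:03d}", description="random", genes=extra)
        )

    # --- survival: exponential, hazard doubled (by default) in the top-P third
    n_high = math.ceil(n / 3)
    order = np.argsort(-P, kind="mergesort")
    high = np.zeros(n, dtype=bool)
    high[order[:n_high]] = True
    hazard = config.baseline_hazard * np.exp(config.hazard_log_hr * high)
    t_disease = rng.exponential(1.0 / hazard)
    t_other = rng.exponential(1.0 / config.other_cause_hazard, size=n)
    t_admin = config.admin_censor_months
    time = np.minimum(np.minimum(t_disease, t_other), t_admin)
    disease_death = t_disease <= np.minimum(t_other, t_admin)
    other_death = ~disease_death & (t_other <= t_admin)
    survival = pd.DataFrame(
        {
            "time": np.round(time, 4),
            "event": (disease_death | other_death).astype(int),
            "cause": np.where(disease_death, "disease", np.where(other_death, "other", "")),
        },
        index=pd.Index(samples, name="sample"),
    )

    # --- clinical covariates
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "gender": rng.choice(["F", "M"], size=n, p=[0.8, 0.2]),
                "er_status": rng.choice(["pos", "neg"], size=n, p=[0.7, 0.3]),
                "subtype": subtypes.to_numpy(),
                "os_months": survival["time"].to_numpy(),
                "os_event": survival["event"].to_numpy(),
                "tumor_type": config.cohort_name,
            },
            index=pd.Index(samples, name="sample"),
        )
    )

    # --- mutations
    mut_genes = sorted(rng.choice(genes, size=config.n_mut_genes, replace=False))
    base_rate = rng.uniform(0.2, 1.8, size=config.n_mut_genes) * config.mutation_rate
    rate = np.clip(
        base_rate[:, None] * np.exp(config.mutation_coupling * P[None, :]), 0.0, 1.0
    )
    hits = rng.random((config.n_mut_genes, n)) < rate
    silent = rng.random((config.n_mut_genes, n)) < 0.1
    recs = []
    for gi, g in enumerate(mut_genes):
        for j in np.flatnonzero(hits[gi]):
            vc = "Silent" if silent[gi, j] else "Missense_Mutation"
            recs.append((g, samples[j], vc))
    maf = MafTable(
        pd.DataFrame(recs, columns=["gene", "sample", "variant_class"])
        if recs
        else pd.DataFrame({"gene": [], "sample": [], "variant_class": []})
    )

    truth = SyntheticTruth(
        phenotype=phenotype,
        driver_segments=[seg_ids[d] for d in config.driver_segments],
        driver_signs={
            seg_ids[d]: int(np.sign(w)) for d, w in zip(config.driver_segments, config.driver_weights)
        },
        subtypes=subtypes,
        signature_genes=list(sig_genes),
        phenotype_noise_sd=config.phenotype_noise_sd,
        hazard_log_hr=config.hazard_log_hr,
    )
    return SyntheticCohort(
        config=config,
        seg=seg_table,
        coords=coords,
        expression=expression,
        clinical=clinical,
        survival=survival,
        maf=maf,
        signatures=signatures,
        segment_defs=segment_defs,
        gene_cna=gene_cna,
        truth=truth,
    )


def simulate_multi_cohort(configs: list[SimulationConfig]) -> SyntheticCohort:
    """Generate several cohorts and concatenate them with tumor-type labels.

    Cohort names must be unique; sample ids carry the cohort name and the
    clinical table gains a ``tumor_type`` column usable as a stratification
    variable.  The first cohort's signature/segment definitions are shared
    (all cohorts use the same synthetic genome).
    """
    names = [c.cohort_name for c in configs]
    if len(set(names)) != len(names):
        raise ValidationError("cohort names must be unique")
    if len({(c.n_genes, c.n_chromosomes, c.n_segments) for c in configs}) != 1:
        raise ValidationError("multi-cohort generation requires a shared genome layout")
    first = simulate_cohort(configs[0])
    shared = tuple(first.truth.signature_genes)
    cohorts = [first] + [
        simulate_cohort(replace(c, signature_genes=shared)) for c in configs[1:]
    ]
    seg = SegmentationTable(pd.concat([c.seg.df for c in cohorts], ignore_index=True))
    expression = pd.concat([c.expression for c in cohorts], axis=1)
    clinical = ClinicalTable(pd.concat([c.clinical.df for c in cohorts]))
    survival = pd.concat([c.survival for c in cohorts])
    maf = MafTable(pd.concat([c.maf.df for c in cohorts], ignore_index=True))
    gene_cna = pd.concat([c.gene_cna for c in cohorts], axis=1)
    truth = SyntheticTruth(
        phenotype=pd.concat([c.truth.phenotype for c in cohorts]),
        driver_segments=first.truth.driver_segments,
        driver_signs=first.truth.driver_signs,
        subtypes=pd.concat([c.truth.subtypes for c in cohorts]),
        signature_genes=first.truth.signature_genes,
        phenotype_noise_sd=first.truth.phenotype_noise_sd,
        hazard_log_hr=first.truth.hazard_log_hr,
    )
    return SyntheticCohort(
        config=first.config,
        seg=seg,
        coords=first.coords,
        expression=expression,
        clinical=clinical,
        survival=survival,
        maf=maf,
        signatures=first.signatures,
        segment_defs=first.segment_defs,
        gene_cna=gene_cna,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every cohort component in its standard text format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "seg": outdir / "copy_number.seg",
        "coords": outdir / "genes.bed",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "survival": outdir / "survival.tsv",
        "maf": outdir / "mutations.maf",
        "gmt": outdir / "signatures.gmt",
        "segment_defs": outdir / "segments.tsv",
        "truth": outdir / "truth.json",
    }
    write_seg(cohort.seg, paths["seg"])
    write_gene_coords(cohort.coords, paths["coords"])
    write_expression_matrix(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    surv = cohort.survival.copy()
    surv.index.name = "sample"
    surv.to_csv(paths["survival"], sep="\t")
    write_maf(cohort.maf, paths["maf"])
    write_gmt(cohort.signatures, paths["gmt"])
    write_segment_definitions(cohort.segment_defs, paths["segment_defs"])
    truth = {
        "phenotype": {k: float(v) for k, v in cohort.truth.phenotype.items()},
        "driver_segments": cohort.truth.driver_segments,
        "driver_signs": cohort.truth.driver_signs,
        "subtypes": {k: str(v) for k, v in cohort.truth.subtypes.items()},
        "signature_genes": cohort.truth.signature_genes,
        "phenotype_noise_sd": cohort.truth.phenotype_noise_sd,
        "hazard_log_hr": cohort.truth.hazard_log_hr,
        "config": asdict(cohort.config),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
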