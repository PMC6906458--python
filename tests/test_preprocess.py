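"""Normalization pipeline, extreme-method gene CNA, segment features, mutations."""

import math

import numpy as np
import pandas as pd
import pytest

from cnascape import preprocess as pp
from cnascape.errors import ValidationError
from cnascape.io import GeneCoords, MafTable, SegmentDefinitionTable, SegmentationTable


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_upper_quartile_log2_hand_computed():
    # positive values of the sample have 75th percentile 50; a count of 5
    # becomes 5/50*1000 = 100, i.e. log2(101) after the pseudocount.
    col = pd.DataFrame({"S1": [5.0, 10.0, 20.0, 50.0, 50.0]}, index=list("ABCDE"))
    out = pp.upper_quartile_log2(col, scale=1000.0)
    assert out.values.loc["A", "S1"] == pytest.approx(math.log2(101.0), abs=1e-12)


def test_upper_quartile_scale_invariance_and_symmetry(rng):
    x = pd.DataFrame(
        rng.poisson(20, size=(30, 4)).astype(float),
        index=[f"G{i}" for i in range(30)],
        columns=list("abcd"),
    )
    x["b"] = x["a"]  # identical samples -> identical output columns
    out = pp.upper_quartile_log2(x).values
    pd.testing.assert_series_equal(out["a"], out["b"], check_names=False)
    doubled = x.copy()
    doubled["c"] = 2 * x["c"]
    out2 = pp.upper_quartile_log2(doubled).values
    np.testing.assert_allclose(out2["c"], out["c"], atol=1e-12)


def test_upper_quartile_rejects_all_zero_sample():
    x = pd.DataFrame({"S1": [0.0, 0.0]}, index=["G1", "G2"])
    with pytest.raises(ValidationError, match="S1"):
        pp.upper_quartile_log2(x)


@pytest.mark.parametrize("n_expressed,kept", [(7, False), (8, True)])
def test_filter_expressed_is_strictly_greater(n_expressed, kept):
    # "over 70%" is strict: 7/10 is dropped, 8/10 retained
    vals = [1.0] * n_expressed + [0.0] * (10 - n_expressed)
    x = pd.DataFrame([vals], index=["G1"], columns=[f"S{i}" for i in range(10)])
    out = pp.filter_expressed(x, fraction=0.7)
    assert ("G1" in out.values.index) is kept


def test_filter_expressed_fraction_zero_keeps_any_expressed():
    x = pd.DataFrame(
        [[1.0] + [0.0] * 9, [0.0] * 10],
        index=["G1", "G2"],
        columns=[f"S{i}" for i in range(10)],
    )
    out = pp.filter_expressed(x, fraction=0.0)
    assert list(out.values.index) == ["G1"]


def test_median_center_and_standardize(rng):
    x = pd.DataFrame(
        rng.normal(5, 2, size=(40, 12)),
        index=[f"G{i}" for i in range(40)],
        columns=[f"S{i}" for i in range(12)],
    )
    centered = pp.median_center_genes(x)
    assert np.abs(centered.values.median(axis=1)).max() < 1e-9
    # idempotence of centering
    again = pp.median_center_genes(centered.values)
    np.testing.assert_allclose(again.values.values, centered.values.values, atol=1e-12)
    std = pp.standardize_samples(centered)
    assert np.abs(std.values.std(axis=0, ddof=1) - 1).max() < 1e-9
    assert np.abs(std.values.mean(axis=0)).max() < 1e-9


def test_gene_row_centering_example():
    x = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"], columns=list("abc"))
    out = pp.median_center_genes(x).values
    np.testing.assert_allclose(out.loc["G1"], [-1.0, 0.0, 1.0])


def test_standardize_rejects_zero_variance_sample():
    x = pd.DataFrame({"S1": [1.0, 1.0, 1.0], "S2": [1.0, 2.0, 3.0]})
    with pytest.raises(ValidationError, match="S1"):
        pp.standardize_samples(x)


def test_pipeline_stage_order_enforced(rng):
    x = pd.DataFrame(
        rng.poisson(30, size=(10, 8)).astype(float) + 1,
        index=[f"G{i}" for i in range(10)],
        columns=[f"S{i}" for i in range(8)],
    )
    std = pp.standardize_samples(pp.median_center_genes(pp.filter_expressed(x, 0.0)))
    with pytest.raises(ValidationError):
        pp.upper_quartile_log2(std)  # no going back to raw
    with pytest.raises(ValidationError):
        pp.filter_expressed(std)  # filter must precede centering
    with pytest.raises(ValidationError):
        pp.median_center_genes(std)


# ---------------------------------------------------------------------------
# extreme method
# ---------------------------------------------------------------------------


def _seg(records):
    return SegmentationTable(
        pd.DataFrame(records, columns=["sample", "chrom", "start", "end", "value"])
    )


def _coords(records):
    return GeneCoords(pd.DataFrame(records, columns=["gene", "chrom", "start", "end"]))


def test_extreme_gene_within_single_segment():
    seg = _seg([("S1", "1", 0, 1000, 0.7)])
    coords = _coords([("G1", "1", 100, 200)])
    out = pp.gene_cna_extreme(seg, coords)
    assert out.loc["G1", "S1"] == 0.7


@pytest.mark.parametrize(
    "values,expected",
    [((0.8, -0.3), 0.8), ((0.3, -0.8), -0.8), ((0.5, -0.5), 0.5)],
)
def test_extreme_multi_overlap_takes_max_magnitude(values, expected):
    # tie in magnitude resolves to the amplification
    seg = _seg([("S1", "1", 0, 500, values[0]), ("S1", "1", 500, 1000, values[1])])
    coords = _coords([("G1", "1", 400, 600)])
    out = pp.gene_cna_extreme(seg, coords)
    assert out.loc["G1", "S1"] == expected


def test_extreme_no_overlap_is_missing():
    seg = _seg([("S1", "1", 0, 100, 0.5)])
    coords = _coords([("G1", "2", 0, 50), ("G2", "1", 200, 300)])
    out = pp.gene_cna_extreme(seg, coords)
    assert out["S1"].isna().all()


def _extreme_bruteforce(seg_df, gene):
    """Independent oracle: scan every overlapping segment, pick max |value|."""
    vals = []
    for _, s in seg_df.iterrows():
        if s["chrom"] == gene["chrom"] and s["start"] < gene["end"] and s["end"] > gene["start"]:
            vals.append(s["value"])
    if not vals:
        return np.nan
    hi, lo = max(vals), min(vals)
    return hi if abs(hi) >= abs(lo) else lo


def test_extreme_matches_bruteforce_on_random_layouts(rng):
    """Exact agreement with exhaustive overlap enumeration on random layouts."""
    for _ in range(200):
        # random disjoint segments on one chromosome
        cuts = np.sort(rng.choice(np.arange(1, 100), size=rng.integers(2, 8), replace=False))
        bounds = np.concatenate([[0], cuts, [100]]) * 10
        keep = rng.random(len(bounds) - 1) < 0.7
        seg_records = [
            ("S1", "1", int(bounds[i]), int(bounds[i + 1]), float(rng.normal(0, 0.6)))
            for i in range(len(bounds) - 1)
            if keep[i]
        ]
        if not seg_records:
            continue
        a = int(rng.integers(0, 990))
        gene = {"gene": "G1", "chrom": "1", "start": a, "end": a + int(rng.integers(5, 120))}
        seg = _seg(seg_records)
        coords = _coords([tuple(gene.values())])
        got = pp.gene_cna_extreme(seg, coords).loc["G1", "S1"]
        want = _extreme_bruteforce(seg.df, gene)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == want


# ---------------------------------------------------------------------------
# segment scores & panel restriction
# ---------------------------------------------------------------------------


def test_segment_scores_mean_identity_and_oracle(rng):
    genes = [f"G{i}" for i in range(60)]
    g = pd.DataFrame(
        rng.normal(0, 1, size=(60, 5)), index=genes, columns=[f"S{i}" for i in range(5)]
    )
    defs = SegmentDefinitionTable(
        members={"segA": ["G0", "G1"], "segB": ["G2"], "segC": genes[10:60]}
    )
    g.loc["G0"] = 0.2
    g.loc["G1"] = 0.4
    out = pp.segment_scores(g, defs)
    np.testing.assert_allclose(out.loc["segA"], 0.3, atol=1e-12)
    np.testing.assert_allclose(out.loc["segB"], g.loc["G2"], atol=0)
    # independent summation oracle on a 50-gene segment
    brute = g.loc[genes[10:60]].to_numpy().sum(axis=0) / 50
    np.testing.assert_allclose(out.loc["segC"].to_numpy(), brute, atol=1e-12)


def test_segment_scores_linearity(rng):
    genes = [f"G{i}" for i in range(20)]
    g = pd.DataFrame(rng.normal(size=(20, 6)), index=genes, columns=[f"S{i}" for i in range(6)])
    defs = SegmentDefinitionTable(members={"s1": genes[:7], "s2": genes[7:]})
    a = pp.segment_scores(g, defs)
    b = pp.segment_scores(3.5 * g, defs)
    np.testing.assert_allclose(b.to_numpy(), 3.5 * a.to_numpy(), atol=1e-12)


def test_segment_scores_missing_members(rng):
    g = pd.DataFrame({"S1": [0.1, np.nan]}, index=["G1", "G2"])
    defs = SegmentDefinitionTable(members={"s1": ["G1", "G2"], "s2": ["G2"], "s3": ["GX"]})
    out = pp.segment_scores(g, defs)
    assert out.loc["s1", "S1"] == pytest.approx(0.1)  # non-missing mean
    assert np.isnan(out.loc["s2", "S1"])  # all members missing
    assert np.isnan(out.loc["s3", "S1"])  # no resolvable members


def test_restrict_panel(rng):
    g = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"G{i}" for i in range(10)])
    assert pp.restrict_panel(g, g.index).equals(g)
    assert len(pp.restrict_panel(g, ["G1", "G2", "NOPE"])) == 2
    with pytest.raises(ValidationError, match="disjoint"):
        pp.restrict_panel(g, ["NOPE"])


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------


def test_mutation_matrix_filters_classes_and_collapses():
    maf = MafTable(
        pd.DataFrame(
            {
                "gene": ["G1", "G2", "G1"],
                "sample": ["S1", "S1", "S1"],
                "variant_class": ["Missense_Mutation", "Silent", "Nonsense_Mutation"],
            }
        )
    )
    mat, load = pp.mutation_matrix(maf)
    assert mat.loc["G1", "S1"] == 1  # two retained records still 1
    assert "G2" not in mat.index  # Silent filtered out
    assert load["S1"] == 1


def test_mutation_matrix_empty_maf():
    maf = MafTable(pd.DataFrame({"gene": [], "sample": [], "variant_class": []}))
    mat, load = pp.mutation_matrix(maf, samples=["S1", "S2"])
    assert mat.shape == (0, 2)
    assert (load == 0).all()


def test_filter_mutation_genes_rules():
    mat = pd.DataFrame(
        np.zeros((4, 100), dtype=int),
        index=["FREQ6", "FREQ5", "HLA-A", "RARE"],
        columns=[f"S{i}" for i in range(100)],
    )
    mat.iloc[0, :6] = 1  # 6% > 5% -> kept
    mat.iloc[1, :5] = 1  # exactly 5% -> dropped (strict)
    mat.iloc[2, :50] = 1  # HLA prefix -> always dropped
    mat.iloc[3, :1] = 1  # 1%, but on keep list
    out = pp.filter_mutation_genes(mat, keep_list=["RARE"])
    assert list(out.index) == ["FREQ6", "RARE"]
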