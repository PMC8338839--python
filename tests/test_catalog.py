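"""Catalog parsing, filtering, representative selection and trait clustering."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pleiobgs import catalog
from pleiobgs.errors import ConfigurationError

COLS = ["SNPS", "CHR_ID", "CHR_POS", "MAPPED_GENE", "DISEASE/TRAIT",
        "STUDY ACCESSION", "P-VALUE", "EFFECT_KIND", "OR or BETA",
        "RISK ALLELE FREQUENCY"]


def write_catalog(path, rows):
    pd.DataFrame(rows, columns=COLS).to_csv(path, sep="\t", index=False)
    return path


def row(snp="rs1", chrom="1", pos=1000, gene="G1", trait="T1", study="S1",
        p="1e-9", kind="beta", effect="0.1", raf="0.3"):
    return [snp, chrom, pos, gene, trait, study, p, kind, effect, raf]


def test_parse_drops_incomplete_rows_and_counts(tmp_path):
    path = write_catalog(tmp_path / "cat.tsv", [
        row(snp="rs1"),
        row(snp="rs2", raf=""),          # blank frequency
        row(snp="rs3", pos=2000),
    ])
    records, report = catalog.parse_catalog(path)
    assert len(records) == 2
    assert report.n_dropped_incomplete == 1
    assert set(records["snp_id"]) == {"rs1", "rs3"}


def test_parse_missing_column_is_configuration_error(tmp_path):
    df = pd.DataFrame([row()], columns=COLS).drop(columns=["P-VALUE"])
    path = tmp_path / "cat.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ConfigurationError, match="P-VALUE"):
        catalog.parse_catalog(path)


def test_parse_empty_file_warns(tmp_path):
    path = write_catalog(tmp_path / "cat.tsv", [])
    with pytest.warns(UserWarning):
        records, report = catalog.parse_catalog(path)
    assert len(records) == 0 and report.n_rows == 0


def test_parse_normalizes_chromosomes_and_drops_nonautosomal(tmp_path):
    path = write_catalog(tmp_path / "cat.tsv", [
        row(snp="rs1", chrom="chr2"),
        row(snp="rs2", chrom="X"),
        row(snp="rs3", chrom="CHR17", pos=5),
    ])
    records, report = catalog.parse_catalog(path)
    assert list(records["chrom"]) == ["2", "17"]
    assert report.n_dropped_nonautosomal == 1


def test_round_trip_of_generator_catalog(tmp_path, small_bundle):
    """The synthetic catalog round-trips numeric fields bit-identically."""
    records, report = catalog.parse_catalog(small_bundle["paths"]["catalog"])
    truth = small_bundle["truth_observations"].set_index("snp_id")
    got = records.set_index("snp_id")
    common = truth.index.intersection(got.index)
    assert len(common) == len(truth)  # every true observation parsed back
    for col in ("p_value", "effect_value", "risk_allele_freq"):
        np.testing.assert_array_equal(got.loc[common, col].to_numpy(dtype=float),
                                      truth.loc[common, col].to_numpy(dtype=float))
    assert report.n_dropped_incomplete == 0


def test_significance_boundary_is_kept():
    records = pd.DataFrame({
        "p_value": [1e-9, 5e-8, 6e-8],
        "snp_id": ["a", "b", "c"],
    })
    kept = catalog.filter_significant(records)
    assert list(kept["snp_id"]) == ["a", "b"]
    assert len(catalog.filter_significant(records.iloc[:0])) == 0


def test_significant_count_matches_linear_scan(rng):
    p = 10.0 ** (-rng.uniform(2, 12, size=1000))
    records = pd.DataFrame({"p_value": p, "snp_id": [f"rs{i}" for i in range(1000)]})
    kept = catalog.filter_significant(records)
    assert len(kept) == sum(1 for x in p if x <= 5e-8)


def _records_frame(rows):
    return pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "pos", "mapped_gene", "trait", "study_id",
        "p_value", "effect_kind", "effect_value", "risk_allele_freq"])


def test_representative_takes_lowest_p_and_is_order_stable(rng):
    rows = [
        ("rs1", "1", 100, "G", "T", "S1", 1e-10, "beta", 0.1, 0.3),
        ("rs2", "1", 200, "G", "T", "S1", 1e-9, "beta", 0.4, 0.3),
    ]
    records = _records_frame(rows)
    loci = catalog.select_representative(records)
    assert len(loci) == 1 and loci.loc[0, "snp_id"] == "rs1"
    assert loci.loc[0, "maf"] == 0.3

    single = catalog.select_representative(records.iloc[:1])
    assert single.loc[0, "snp_id"] == "rs1"

    # permutation invariance on a grouped random table
    genes = rng.integers(0, 40, size=200)
    traits = rng.integers(0, 5, size=200)
    records = _records_frame([
        (f"rs{i}", "1", 100 + i, f"G{g}", f"T{t}", "S1",
         float(10.0 ** -rng.uniform(8, 15)), "beta", float(rng.normal()), 0.4)
        for i, (g, t) in enumerate(zip(genes, traits))])
    base = catalog.select_representative(records)
    for _ in range(3):
        shuffled = records.iloc[rng.permutation(len(records))].reset_index(drop=True)
        pd.testing.assert_frame_equal(catalog.select_representative(shuffled), base)
    # brute-force group-by-minimum oracle
    expect = {(g, t): grp.loc[grp["p_value"].idxmin(), "snp_id"]
              for (g, t), grp in records.groupby(["mapped_gene", "trait"])}
    got = {(r.locus_id, r.trait): r.snp_id for r in base.itertuples()}
    assert got == expect
    assert len(base) == records.groupby(["mapped_gene", "trait"]).ngroups


def test_representative_tie_break_prefers_larger_effect_then_snp_id():
    rows = [
        ("rs_b", "1", 100, "G", "T", "S1", 1e-9, "beta", 0.1, 0.3),
        ("rs_a", "1", 200, "G", "T", "S1", 1e-9, "beta", 0.5, 0.3),
        ("rs_c", "1", 300, "G", "T", "S1", 1e-9, "beta", 0.5, 0.3),
    ]
    loci = catalog.select_representative(_records_frame(rows))
    assert loci.loc[0, "snp_id"] == "rs_a"  # largest |effect|, then lexicographic


def test_trait_filter_thresholds():
    rows = []
    for i in range(29):  # 29 genes, 5 studies -> below gene threshold
        rows.append((f"a{i}", "1", i, f"GA{i}", "TA", f"SA{i % 5}", 1e-9, "beta", 0.1, 0.3))
    for i in range(40):  # 40 genes, 2 studies -> below study threshold
        rows.append((f"b{i}", "1", i, f"GB{i}", "TB", f"SB{i % 2}", 1e-9, "beta", 0.1, 0.3))
    for i in range(31):  # passes both
        rows.append((f"c{i}", "1", i, f"GC{i}", "TC", f"SC{i % 3}", 1e-9, "beta", 0.1, 0.3))
    records = _records_frame(rows)
    loci = catalog.select_representative(records)
    kept_loci, kept = catalog.filter_traits(loci, records)
    assert kept == ["TC"]
    assert set(kept_loci["trait"]) == {"TC"} and len(kept_loci) == 31


def test_trait_filter_matches_generator_truth(small_bundle):
    from pleiobgs.catalog import parse_catalog, filter_significant, select_representative, filter_traits
    records, _ = parse_catalog(small_bundle["paths"]["catalog"])
    significant = filter_significant(records)
    loci = select_representative(significant)
    _, kept = filter_traits(loci, significant, min_genes=10, min_studies=3)
    assert kept == small_bundle["truth_params"]["traits"]


def _loci_frame(pairs):
    return pd.DataFrame([{"trait": t, "locus_id": g} for t, g in pairs])


def test_cluster_identical_and_disjoint_sets():
    loci = _loci_frame([("T1", "G1"), ("T1", "G2"), ("T2", "G1"), ("T2", "G2")])
    assert catalog.cluster_traits(loci, 0.5) == {"T1": "T1", "T2": "T1"}
    loci = _loci_frame([("T1", "G1"), ("T2", "G2")])
    mapping = catalog.cluster_traits(loci, 0.5)
    assert mapping == {"T1": "T1", "T2": "T2"}


def test_cluster_threshold_extremes():
    loci = _loci_frame([("T1", "G1"), ("T1", "G2"), ("T2", "G2"), ("T3", "G9")])
    # threshold 1.0 merges only identical sets
    assert catalog.cluster_traits(loci, 1.0) == {"T1": "T1", "T2": "T2", "T3": "T3"}
    # threshold near zero merges anything sharing a gene
    mapping = catalog.cluster_traits(loci, 1e-9)
    assert mapping["T1"] == mapping["T2"] == "T1" and mapping["T3"] == "T3"


def test_cluster_matches_pairwise_jaccard_components_oracle(rng):
    traits = [f"T{i}" for i in range(10)]
    gene_sets = {}
    pool = [f"G{i}" for i in range(25)]
    base = set(rng.choice(pool, size=8, replace=False))
    for i, t in enumerate(traits):
        if i < 4:  # planted overlapping block
            extra = set(rng.choice(pool, size=2, replace=False))
            gene_sets[t] = set(base) | extra
        else:
            gene_sets[t] = set(rng.choice(pool, size=5, replace=False))
    loci = _loci_frame([(t, g) for t, gs in gene_sets.items() for g in gs])
    threshold = 0.5
    mapping = catalog.cluster_traits(loci, threshold)

    g = nx.Graph()
    g.add_nodes_from(traits)
    for a, b in combinations(traits, 2):
        inter = len(gene_sets[a] & gene_sets[b])
        union = len(gene_sets[a] | gene_sets[b])
        if union and inter / union >= threshold:
            g.add_edge(a, b)
    expected = {}
    for comp in nx.connected_components(g):
        rep = min(comp)
        for t in comp:
            expected[t] = rep
    assert mapping == expected


def test_apply_clusters_rededuplicates():
    loci = pd.DataFrame({
        "trait": ["T1", "T2"], "locus_id": ["G", "G"],
        "snp_id": ["rs1", "rs2"], "p_value": [1e-9, 1e-12],
        "effect_kind": ["beta", "beta"], "effect_value": [0.1, 0.2],
    })
    merged = catalog.apply_trait_clusters(loci, {"T1": "T1", "T2": "T1"})
    assert len(merged) == 1 and merged.loc[0, "snp_id"] == "rs2"
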