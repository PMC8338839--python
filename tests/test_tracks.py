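"""Stepped-track IO and queries against per-base brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pleiobgs import tracks
from pleiobgs.errors import ConfigurationError, FormatError


def make_track(segs, kind="B"):
    df = pd.DataFrame(segs, columns=["chrom", "start", "end", "value"])
    return tracks.SteppedTrack.from_frame(kind, df)


def random_dyadic_track(rng, chrom="1", n_segs=12, span=400):
    """Sorted segments with gaps; dyadic values so sums are exact."""
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_segs, replace=False))
    segs = []
    for i in range(n_segs):
        s, e = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if s < e:
            segs.append((chrom, s, e, int(rng.integers(0, 9)) / 8.0))
    return segs


def expand_per_base(segs, chrom, start, end):
    """Per-base value array over [start, end); NaN where uncovered."""
    arr = np.full(end - start, np.nan)
    for c, s, e, v in segs:
        if c != chrom:
            continue
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            arr[lo - start:hi - start] = v
    return arr


# --- bedGraph reader -------------------------------------------------------

def test_read_bedgraph_scaling_and_sort_invariance(tmp_path):
    p = tmp_path / "a.bedgraph"
    p.write_text("1 0 100 800\n")
    t = tracks.read_bedgraph(p, value_kind="B", b_scale=1000)
    assert t.segments["1"][2][0] == 0.8

    # auto-detection: max > 1 implies integer scale
    p.write_text("1 0 100 800\n1 100 200 950\n")
    t = tracks.read_bedgraph(p, value_kind="B")
    np.testing.assert_allclose(t.segments["1"][2], [0.8, 0.95])

    p2 = tmp_path / "b.bedgraph"
    p.write_text("1 100 200 0.5\n1 0 100 0.25\n")
    p2.write_text("1 0 100 0.25\n1 100 200 0.5\n")
    ta, tb = tracks.read_bedgraph(p), tracks.read_bedgraph(p2)
    for a, b in zip(ta.segments["1"], tb.segments["1"]):
        np.testing.assert_array_equal(a, b)


def test_read_bedgraph_rejects_overlaps_and_bad_numbers(tmp_path):
    p = tmp_path / "bad.bedgraph"
    p.write_text("1 0 100 0.5\n1 50 150 0.6\n")
    with pytest.raises(FormatError, match="line 2"):
        tracks.read_bedgraph(p)
    p.write_text("1 0 100 high\n")
    with pytest.raises(FormatError, match="line 1"):
        tracks.read_bedgraph(p)


def test_bedgraph_round_trip_matches_generator_truth(tmp_path, small_bundle):
    t = tracks.read_bedgraph(small_bundle["paths"]["b_track"], value_kind="B")
    truth = small_bundle["b_track"]
    for chrom, grp in truth.groupby("chrom"):
        starts, ends, values = t.segments[str(chrom)]
        grp = grp.sort_values("start")
        np.testing.assert_array_equal(starts, grp["start"])
        np.testing.assert_array_equal(ends, grp["end"])
        np.testing.assert_array_equal(values, grp["value"])


# --- genetic map reader ----------------------------------------------------

def test_read_genetic_map_basics(tmp_path):
    p = tmp_path / "map.txt"
    p.write_text("Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n"
                 "1\t0\t1.5\t0.0\n1\t1000\t0\t0.0015\n")
    t = tracks.read_genetic_map(p)
    starts, ends, values = t.segments["1"]
    assert list(starts) == [0] and list(ends) == [1000] and list(values) == [1.5]

    p.write_text("1\t500\t2.0\t0.0\n")
    with pytest.warns(UserWarning, match="single"):
        t = tracks.read_genetic_map(p)
    assert t.segments == {}

    p.write_text("1\t1000\t1.0\t0\n1\t500\t2.0\t1\n")
    with pytest.raises(FormatError, match="line 2"):
        tracks.read_genetic_map(p)


def test_genetic_map_cumulative_integration_oracle(tmp_path, rng):
    """The written Map(cM) column re-integrates from the parsed segments."""
    pos = np.sort(rng.choice(np.arange(0, 10_000_000, 1000), size=50, replace=False))
    rates = np.round(rng.uniform(0, 5, size=50), 4)
    cum = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(pos) / 1e6)])
    lines = ["Chromosome Position(bp) Rate(cM/Mb) Map(cM)"]
    lines += [f"7 {p} {r} {c}" for p, r, c in zip(pos, rates, cum)]
    path = tmp_path / "map.txt"
    path.write_text("\n".join(lines) + "\n")
    t = tracks.read_genetic_map(path)
    starts, ends, values = t.segments["7"]
    rebuilt = np.concatenate([[0.0], np.cumsum(values * (ends - starts) / 1e6)])
    np.testing.assert_allclose(rebuilt, cum, atol=1e-6)


# --- queries ---------------------------------------------------------------

def test_point_value_boundaries():
    t = make_track([("1", 0, 100, 0.8)])
    assert t.point_value("1", 100) == 0.8      # 1-based pos 100 = last covered base
    assert math.isnan(t.point_value("1", 101))
    assert math.isnan(t.point_value("2", 50))


def test_point_value_matches_linear_scan(rng):
    segs = random_dyadic_track(rng, n_segs=20, span=1000)
    t = make_track(segs)
    arr = expand_per_base(segs, "1", 0, 1000)
    for pos in rng.integers(1, 1001, size=1000):
        got = t.point_value("1", int(pos))
        want = arr[pos - 1]
        assert (math.isnan(got) and math.isnan(want)) or got == want


def test_interval_mean_constants_and_steps():
    t = make_track([("1", 0, 1000, 0.8)])
    mean, cov = t.interval_mean("1", 10, 500)
    assert mean == 0.8 and cov == 1.0
    t = make_track([("1", 0, 100, 0.2), ("1", 100, 200, 0.4)])
    mean, cov = t.interval_mean("1", 0, 200)
    assert mean == pytest.approx(0.3) and cov == 1.0
    mean, cov = t.interval_mean("1", 500, 600)
    assert math.isnan(mean) and cov == 0.0
    with pytest.raises(ConfigurationError):
        t.interval_mean("1", 10, 10)


def test_interval_mean_matches_per_base_brute_force(rng):
    for _ in range(50):
        segs = random_dyadic_track(rng)
        t = make_track(segs)
        s = int(rng.integers(0, 390))
        e = int(rng.integers(s + 1, 401))
        mean, cov = t.interval_mean("1", s, e)
        arr = expand_per_base(segs, "1", s, e)
        covered = ~np.isnan(arr)
        if covered.sum() == 0:
            assert math.isnan(mean) and cov == 0.0
        else:
            assert mean == float(arr[covered].sum() / covered.sum())  # exact: dyadic values
            assert cov == covered.sum() / (e - s)
        lo, hi = min(v for *_, v in segs), max(v for *_, v in segs)
        if not math.isnan(mean):
            assert lo <= mean <= hi


@settings(derandomize=True, max_examples=50)
@given(split=st.integers(1, 399))
def test_interval_mean_split_reweighting(split):
    rng = np.random.default_rng(5)
    segs = random_dyadic_track(rng)
    t = make_track(segs)
    whole, cov = t.interval_mean("1", 0, 400)
    m1, c1 = t.interval_mean("1", 0, split)
    m2, c2 = t.interval_mean("1", split, 400)
    w1 = c1 * split
    w2 = c2 * (400 - split)
    if w1 + w2 == 0:
        assert math.isnan(whole)
    else:
        parts = (0.0 if w1 == 0 else m1 * w1) + (0.0 if w2 == 0 else m2 * w2)
        assert parts / (w1 + w2) == pytest.approx(whole, abs=1e-12)


# --- MHC masking -----------------------------------------------------------

def test_mhc_mask_point_boundaries_and_idempotence():
    snps = pd.DataFrame({
        "chrom": ["6", "6", "6", "2"],
        "pos": [26_000_000, 24_999_999, 25_000_000, 26_000_000],
    })
    kept, n = tracks.mhc_mask(snps)
    assert n == 2
    assert list(kept["pos"]) == [24_999_999, 26_000_000]
    again, n2 = tracks.mhc_mask(kept)
    assert n2 == 0
    pd.testing.assert_frame_equal(again, kept)


def test_mhc_mask_interval_overlap_matches_brute_force(rng):
    items = pd.DataFrame({
        "chrom": rng.choice(["5", "6"], size=300),
        "start": rng.integers(0, 50_000_000, size=300),
    })
    items["end"] = items["start"] + rng.integers(1, 5_000_000, size=300)
    kept, n = tracks.mhc_mask(items)
    lo0, hi0 = 25_000_000 - 1, 34_000_000  # window in 0-based half-open coords
    expect = [not (c == "6" and s < hi0 and e > lo0)
              for c, s, e in items[["chrom", "start", "end"]].itertuples(index=False)]
    assert n == 300 - sum(expect)
    assert list(kept["start"]) == list(items.loc[expect, "start"])


# --- gene interval readers -------------------------------------------------

def test_read_gene_intervals_bed_and_gff3(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("1\t999\t2000\tG1\n")
    out = tracks.read_gene_intervals(bed, fmt="bed")
    assert tuple(out.iloc[0]) == ("1", 999, 2000, "G1")

    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=G1;Name=G1\n")
    out2 = tracks.read_gene_intervals(gff, fmt="gff3")
    assert tuple(out2.iloc[0]) == ("1", 999, 2000, "G1")

    bed.write_text("1\t2000\t999\tG1\n")
    with pytest.raises(FormatError, match="line 1"):
        tracks.read_gene_intervals(bed, fmt="bed")


def test_duplicate_gene_names_union_span(tmp_path):
    bed = tmp_path / "g.bed"
    bed.write_text("1\t100\t200\tG1\n1\t150\t400\tG1\n1\t500\t600\tG2\n")
    with pytest.warns(UserWarning, match="duplicate"):
        out = tracks.read_gene_intervals(bed, fmt="bed")
    g1 = out[out["label"] == "G1"].iloc[0]
    assert (g1["start"], g1["end"]) == (100, 400)


def test_gff3_round_trip_matches_generator_truth(small_bundle):
    out = tracks.read_gene_intervals(small_bundle["paths"]["genes_gff3"], fmt="gff3")
    truth = small_bundle["genes"]
    merged = out.set_index("label").join(truth.set_index("locus_id"), rsuffix="_t")
    assert len(merged) == len(truth)
    assert (merged["start"] == merged["start_t"]).all()
    assert (merged["end"] == merged["end_t"]).all()


# --- annotation ------------------------------------------------------------

def test_annotate_constant_genome_snp_level():
    b = make_track([("1", 0, 10_000, 0.7)])
    rr = make_track([("1", 0, 10_000, 1.0)], kind="RR")
    snps = pd.DataFrame({"chrom": ["1"], "pos": [500], "locus_id": ["G1"], "degree": [2]})
    out = tracks.annotate(snps, b, rr, level="snp")
    assert out.loc[0, "B"] == 0.7
    assert out.loc[0, "RR"] == 1.0
    assert out.loc[0, "log10RR"] == 0.0
    assert bool(out.loc[0, "complete"])


def test_annotate_gene_level_requires_gene_table():
    b = make_track([("1", 0, 10_000, 0.7)])
    rr = make_track([("1", 0, 10_000, 1.0)], kind="RR")
    profiles = pd.DataFrame({"locus_id": ["G1"], "degree": [1]})
    with pytest.raises(ConfigurationError):
        tracks.annotate(profiles, b, rr, level="gene", genes=None)
    genes = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200], "label": ["G1"]})
    out = tracks.annotate(profiles, b, rr, level="gene", genes=genes)
    assert out.loc[0, "B"] == 0.7


def test_annotate_matches_generator_truth(small_bundle, small_run):
    """Planted per-gene B/RR are recovered exactly for every covered gene."""
    annotated = small_run.annotated.set_index("locus_id")
    truth = small_bundle["truth_loci"].set_index("locus_id")
    joined = annotated.join(truth[["b_true", "rr_true"]])
    np.testing.assert_allclose(joined["B"], joined["b_true"], atol=1e-12)
    np.testing.assert_allclose(joined["RR"], joined["rr_true"], atol=1e-9)


def test_b_values_stay_in_unit_interval(small_bundle, small_run):
    t = tracks.read_bedgraph(small_bundle["paths"]["b_track"], value_kind="B")
    for starts, ends, values in t.segments.values():
        assert (values >= 0).all() and (values <= 1).all()
    ann = small_run.annotated
    assert ann["B"].dropna().between(0, 1).all()
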