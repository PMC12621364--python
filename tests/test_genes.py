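"""Metagene profiles, gbM/teM classification, DMR annotation, allelic pairs."""

import numpy as np
import pandas as pd
import pytest

from panmeth import genes as gn
from panmeth.graph import SequenceGraph, _infer_edges


def _graph(nodes, paths):
    g = SequenceGraph(nodes=dict(nodes), paths={k: list(v) for k, v in paths.items()})
    _infer_edges(g)
    return g


def _profile(sites):
    """sites: (pos 1-based, context, level)."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * len(sites),
            "pos": [s[0] for s in sites],
            "strand": ["+"] * len(sites),
            "context": [s[1] for s in sites],
            "level_mean": [s[2] for s in sites],
        }
    )


def _gene(start, end, strand="+", exons=None, gid="g1"):
    return gn.GeneModel(gid, "chr1", start, end, strand, exons or [(start, end)])


# -- gene model ----------------------------------------------------------


def test_introns_derived_from_exons():
    g = _gene(100, 400, exons=[(100, 180), (220, 300), (350, 400)])
    assert g.introns == [(180, 220), (300, 350)]


def test_promoter_strand_aware_and_clipped():
    plus = _gene(1000, 2000)
    assert plus.promoter(3000) == (0, 1000)
    minus = _gene(1000, 2000, strand="-")
    assert minus.promoter(3000) == (2000, 5000)


def test_gff3_round_trip(tmp_path, small_trio):
    _, truth, _ = small_trio
    p = tmp_path / "genes.gff3"
    gn.write_gff3(truth.genes["CF1"], truth.exons["CF1"], p)
    models = gn.read_gff3(p)
    assert len(models) == len(truth.genes["CF1"])
    expected = gn.genes_from_frames(truth.genes["CF1"], truth.exons["CF1"])
    by_id = {m.gene_id: m for m in models}
    for e in expected:
        m = by_id[e.gene_id]
        assert (m.start, m.end, m.strand, m.exons) == (e.start, e.end, e.strand, e.exons)


# -- metagene ------------------------------------------------------------


def test_metagene_flat_profile():
    sites = [(p, "CG", 50.0) for p in range(1, 4001, 7)]
    prof = _profile(sites)
    gene = _gene(1500, 2500)
    mg = gn.metagene_profile([gene], prof, flank=1000, bins=100)
    cg = mg[mg["context"] == "CG"]
    filled = cg.dropna(subset=["level"])
    assert len(filled) > 250
    assert np.allclose(filled["level"], 50.0)


def test_metagene_minus_strand_orientation():
    # one site 100 bp 3' of the gene in chromosome coordinates: for a
    # minus-strand gene that is 100 bp *upstream* of the TSS
    gene = _gene(2000, 3000, strand="-")
    prof = _profile([(3101, "CG", 80.0)])  # pos0 3100, inside [3000, 4000)
    mg = gn.metagene_profile([gene], prof, flank=1000, bins=100)
    hit = mg[(mg["context"] == "CG") & mg["level"].notna()]
    assert len(hit) == 1
    assert hit["segment"].iloc[0] == "upstream"
    # 100 bp from the TSS -> near the TSS-proximal end of the upstream block
    assert hit["bin"].iloc[0] == 89


def test_metagene_manual_oracle():
    gene = _gene(1000, 1200)  # body bins are 2 bp wide
    sites = [(1001, "CG", 10.0), (1002, "CG", 30.0), (1101, "CG", 90.0)]
    mg = gn.metagene_profile([gene], _profile(sites), flank=1000, bins=100)
    cg = mg[(mg["context"] == "CG") & mg["level"].notna()].set_index("bin")
    # pos0 1000,1001 -> body bin 0 (mean 20); pos0 1100 -> body bin 50
    assert cg.loc[100, "level"] == pytest.approx(20.0)
    assert cg.loc[150, "level"] == pytest.approx(90.0)
    assert len(cg) == 2


# -- gbM / teM -----------------------------------------------------------


def _uniform_gene_profile(gene, cg, chg, chh, n=30):
    """Evenly spaced exonic sites with the given per-context levels."""
    sites = []
    (s, e) = gene.exons[0]
    xs = np.linspace(s + 1, e, n).astype(int)
    for i, p in enumerate(xs):
        ctx = ("CG", "CHG", "CHH")[i % 3]
        lvl = {"CG": cg, "CHG": chg, "CHH": chh}[ctx]
        sites.append((int(p), ctx, lvl))
    return _profile(sites)


@pytest.mark.parametrize(
    "cg,chg,chh,expected",
    [
        (60, 2, 1, "gbM"),
        (60, 30, 10, "teM"),  # fails gbM on CHG, passes >=5 everywhere
        (3, 3, 3, "other"),
        (20, 19.9, 19.9, "gbM"),  # CG boundary inclusive
        (19.9, 30, 30, "teM"),  # fails gbM on CG but >= 5 in all contexts
        (2, 30, 30, "other"),  # CG below the 5% teM floor
    ],
)
def test_classification_rule_examples(cg, chg, chh, expected):
    gene = _gene(100, 700)
    prof = _uniform_gene_profile(gene, cg, chg, chh)
    got = gn.classify_gene_methylation([gene], prof)["meth_class"][0]
    assert got == expected


def test_classification_matches_brute_force(small_trio, small_profiles):
    _, truth, _ = small_trio
    hap = "CF1"
    profile = small_profiles[hap]
    models = gn.genes_from_frames(truth.genes[hap], truth.exons[hap])
    got = gn.classify_gene_methylation(models, profile).set_index("gene_id")
    pos0 = profile["pos"].to_numpy() - 1
    for m in models:
        means = {}
        for c in ("CG", "CHG", "CHH"):
            sel = np.zeros(len(profile), dtype=bool)
            for s, e in m.exons:
                sel |= (pos0 >= s) & (pos0 < e)
            sel &= (profile["context"] == c).to_numpy()
            if sel.any():
                means[c] = profile.loc[sel, "level_mean"].mean()
        if len(means) < 3:
            expected = "other"
        elif means["CG"] >= 20 and means["CHG"] < 20 and means["CHH"] < 20:
            expected = "gbM"
        elif min(means.values()) >= 5:
            expected = "teM"
        else:
            expected = "other"
        assert got.loc[m.gene_id, "meth_class"] == expected


def test_forced_gene_labels_recovered(small_trio, small_profiles):
    _, truth, _ = small_trio
    hap = "CF2"
    models = gn.genes_from_frames(truth.genes[hap], truth.exons[hap])
    cls = gn.classify_gene_methylation(models, small_profiles[hap])
    merged = cls.merge(truth.gene_classes, on="gene_id")
    forced = merged[merged["forced_class"] != "none"]
    assert len(forced) > 0
    assert (forced["meth_class"] == forced["forced_class"]).all()


def test_gene_without_exonic_sites_flagged():
    gene = _gene(100, 200)
    prof = _profile([(500, "CG", 50.0)])
    out = gn.classify_gene_methylation([gene], prof)
    assert out["meth_class"][0] == "other"
    assert out["missing_context"][0] != ""


# -- DMR annotation ------------------------------------------------------


def _dmrs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_annotation_priority_and_te_flag():
    gene = _gene(1000, 2000, exons=[(1000, 1400), (1600, 2000)])
    repeats = pd.DataFrame(
        [{"chrom": "chr1", "start": 1200, "end": 1300, "name": "te1"}]
    )
    dmrs = _dmrs(
        [
            ("chr1", 1250, 1260),  # exon + repeat -> exon, TE flag
            ("chr1", 1450, 1500),  # intron
            ("chr1", 500, 600),  # promoter (3 kb upstream of TSS)
            ("chr1", 5000, 5100),  # nothing
        ]
    )
    out = gn.annotate_regions(dmrs, [gene], repeats)
    assert list(out["feature"]) == ["exon", "intron", "promoter", "intergenic"]
    assert list(out["te_overlap"]) == [True, False, False, False]


def test_annotation_order_invariant():
    g1 = _gene(1000, 2000, gid="a")
    g2 = _gene(4000, 5000, gid="b")
    reps = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 1500, "end": 1600, "name": "r1"},
            {"chrom": "chr1", "start": 4500, "end": 4600, "name": "r2"},
        ]
    )
    dmrs = _dmrs([("chr1", 1550, 1560), ("chr1", 4550, 4560)])
    a = gn.annotate_regions(dmrs, [g1, g2], reps)
    b = gn.annotate_regions(dmrs, [g2, g1], reps.iloc[::-1].reset_index(drop=True))
    pd.testing.assert_frame_equal(a, b)


# -- SV proximity --------------------------------------------------------


def test_sv_length_and_maxgap_rules():
    dmrs = _dmrs([("chr1", 1000, 1200)]).assign(te_overlap=[True])
    svs = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 1100, "end": 1149, "sv_type": "DEL"},  # 49 bp
            {"chrom": "chr1", "start": 1100, "end": 1160, "sv_type": "DEL"},  # within
            {"chrom": "chr1", "start": 2200, "end": 2260, "sv_type": "INS"},  # gap 1000
            {"chrom": "chr1", "start": 2201, "end": 2261, "sv_type": "INS"},  # gap 1001
        ]
    )
    pairs, _ = gn.sv_proximity(dmrs, svs, maxgap=1000)
    assert len(pairs) == 2
    classes = {(p["sv_start"], p["distance_class"]) for _, p in pairs.iterrows()}
    assert (1100, "within") in classes
    assert (2200, "proximal") in classes


# -- allelic pairs -------------------------------------------------------


def test_identical_haplotypes_pair_every_gene():
    g = _graph({"1": "A" * 5000}, {"H1": [("1", "+")], "H2": [("1", "+")]})
    ga = [_gene(100, 600, gid="a1"), _gene(1000, 1500, gid="a2")]
    gb = [_gene(100, 600, gid="b1"), _gene(1000, 1500, gid="b2")]
    pairs, unpaired = gn.allelic_pairs(g, ga, gb, "H1", "H2")
    assert len(pairs) == 2 and unpaired.empty
    assert set(zip(pairs["gene_a"], pairs["gene_b"])) == {("a1", "b1"), ("a2", "b2")}


def test_gene_in_private_insertion_unprojectable():
    g = _graph(
        {"1": "A" * 1000, "I": "G" * 600, "2": "T" * 1000},
        {"H1": [("1", "+"), ("I", "+"), ("2", "+")], "H2": [("1", "+"), ("2", "+")]},
    )
    ga = [_gene(1100, 1500, gid="inside")]  # fully inside the insertion
    pairs, unpaired = gn.allelic_pairs(g, ga, [], "H1", "H2")
    assert pairs.empty
    assert list(unpaired["category"]) == ["unprojectable"]


def test_low_overlap_is_not_a_pair():
    g = _graph({"1": "A" * 5000}, {"H1": [("1", "+")], "H2": [("1", "+")]})
    ga = [_gene(1000, 2000, gid="a")]
    gb = [_gene(1600, 2600, gid="b")]  # 40% of the projected span
    pairs, unpaired = gn.allelic_pairs(g, ga, gb, "H1", "H2")
    assert pairs.empty
    assert set(unpaired["category"]) == {"no_overlap"}


def test_reciprocal_requirement():
    g = _graph({"1": "A" * 5000}, {"H1": [("1", "+")], "H2": [("1", "+")]})
    # b overlaps a's projection by >=50%, but b's best match is c
    ga = [_gene(1000, 2000, gid="a"), _gene(1450, 2100, gid="c")]
    gb = [_gene(1400, 2100, gid="b")]
    pairs, unpaired = gn.allelic_pairs(g, ga, gb, "H1", "H2")
    got = set(zip(pairs["gene_a"], pairs["gene_b"]))
    assert got == {("c", "b")}
    assert "a" in set(unpaired["gene_id"])


# -- inherited sets ------------------------------------------------------


def test_inherited_sets_sign_agreement():
    a = pd.DataFrame({"id": ["g1", "g2", "g3"], "sign": [1, 1, -1]})
    b = pd.DataFrame({"id": ["g1", "g2", "g4"], "sign": [1, -1, 1]})
    out = gn.inherited_sets(a, b)
    assert list(out["id"]) == ["g1"]
    assert list(out["sign"]) == [1]


def test_inherited_sets_disjoint_warns():
    a = pd.DataFrame({"id": ["g1"], "sign": [1]})
    b = pd.DataFrame({"id": ["g2"], "sign": [1]})
    with pytest.warns(UserWarning):
        out = gn.inherited_sets(a, b)
    assert out.empty
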