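"""Synthetic trio generator: genomes, graph, methylomes, bias emulation."""

import numpy as np
import pandas as pd
import pytest

from panmeth.config import HAPLOTYPES, PARENTAL_HAPLOTYPES, TrioConfig
from panmeth.graph import path_sequence, project_position
from panmeth.simulate import (
    cytosine_sites,
    emit_single_reference_calls,
    simulate_annotations,
    simulate_methylomes,
    simulate_trio,
    simulate_trio_genomes,
    write_outputs,
)


# -- genomes and graph ---------------------------------------------------


def test_zero_variation_gives_identical_linear_paths():
    cfg = TrioConfig(
        chrom_length=5_000, snp_rate=0.0, indel_rate=0.0, sv_count=0, seed=0
    )
    truth = simulate_trio_genomes(cfg)
    g = truth.graphs["chr1"]
    seqs = {path_sequence(g, h) for h in HAPLOTYPES}
    assert len(seqs) == 1
    # a single linear chain: every path is the same single node sequence
    assert len({tuple(g.paths[h]) for h in HAPLOTYPES}) == 1
    assert len(g.paths["CF1"]) == 1


def test_paths_spell_truth_sequences(small_trio):
    _, truth, _ = small_trio
    for chrom, g in truth.graphs.items():
        for hap in HAPLOTYPES:
            assert path_sequence(g, hap) == truth.haplotype_sequences[hap][chrom]


def test_cs_haplotypes_copy_one_parent(small_trio):
    _, truth, _ = small_trio
    for chrom in truth.chroms:
        for cs, parents in (("CSCF", ("CF1", "CF2")), ("CSSB", ("SB1", "SB2"))):
            (seg,) = truth.inheritance[chrom][cs]
            assert seg[2] in parents
            assert (
                truth.haplotype_sequences[cs][chrom]
                == truth.haplotype_sequences[seg[2]][chrom]
            )


def test_single_snp_forms_one_bubble():
    """Every truth SNP appears as a 1 bp allele-node bubble between the
    haplotypes that disagree there."""
    cfg = TrioConfig(chrom_length=10_000, seed=6, indel_rate=0.0, sv_count=0)
    truth = simulate_trio_genomes(cfg)
    g = truth.graphs["chr1"]
    snps = truth.variants.query("type == 'SNP'")
    assert len(snps) > 0
    for _, v in snps.head(20).iterrows():
        if v["allele_CF1"] == v["allele_SB1"]:
            continue
        # the differing position does not project between the two paths
        assert project_position(g, "CF1", int(v["pos_CF1"]), "SB1") is None
        # but the flanking bases do
        assert project_position(g, "CF1", int(v["pos_CF1"]) - 1, "SB1") is not None


def test_degenerate_spacing_rejected():
    with pytest.raises(ValueError, match="spacing"):
        simulate_trio_genomes(TrioConfig(chrom_length=5_000, snp_rate=0.2))


def test_determinism_byte_identical():
    cfg = TrioConfig(chrom_length=10_000, seed=42)
    t1, m1 = simulate_trio(cfg, annotations=False)
    t2, m2 = simulate_trio(cfg, annotations=False)
    assert t1.haplotype_sequences == t2.haplotype_sequences
    pd.testing.assert_frame_equal(t1.variants, t2.variants)
    pd.testing.assert_frame_equal(m1["CF1"]["CF_c1"], m2["CF1"]["CF_c1"])
    pd.testing.assert_frame_equal(m1["CSSB"]["CS_c3"], m2["CSSB"]["CS_c3"])


def test_coordinate_maps_bijective(small_trio):
    _, truth, _ = small_trio
    pa, pb = truth.coordinate_map("CF1", "CSSB", "chr1")
    assert len(pa) == len(np.unique(pa)) == len(np.unique(pb))


def test_projection_agrees_with_coordinate_map(small_trio):
    _, truth, _ = small_trio
    g = truth.graphs["chr1"]
    pa, pb = truth.coordinate_map("CF2", "SB1", "chr1")
    rng = np.random.default_rng(0)
    for i in rng.integers(0, len(pa), 300):
        assert project_position(g, "CF2", int(pa[i]), "SB1") == pb[i]


# -- cytosine sites and methylomes --------------------------------------


def test_cytosine_sites_strand_convention():
    # G on the forward strand emits a minus-strand record with the
    # reverse-complement trinucleotide
    sites = cytosine_sites("AAGTC")
    g_row = sites[sites["strand"] == "-"].iloc[0]
    assert g_row["pos0"] == 2
    assert g_row["trinuc"] == "CTT"  # revcomp of AAG read 5'->3' on minus
    assert g_row["context"] == "CHH"
    c_row = sites[sites["strand"] == "+"].iloc[0]
    assert c_row["pos0"] == 4 and c_row["trinuc"] == "CNN"


def test_cytosine_context_classes():
    sites = cytosine_sites("ACGTACAGACTT")
    by_pos = {(r["pos0"], r["strand"]): r["context"] for _, r in sites.iterrows()}
    assert by_pos[(1, "+")] == "CG"
    assert by_pos[(5, "+")] == "CHG"  # CAG
    assert by_pos[(9, "+")] == "CHH"  # CTT


def test_inheritance_identity_without_noise():
    cfg = TrioConfig(chrom_length=10_000, seed=7, epimutation_rate=0.0)
    truth, _ = simulate_trio(cfg, annotations=False)
    for cs in ("CSCF", "CSSB"):
        src = truth.inheritance["chr1"][cs][0][2]
        a = truth.site_states[cs]
        b = truth.site_states[src]
        assert (a["level"].to_numpy() == b["level"].to_numpy()).all()


def test_binomial_count_expectation():
    """Mean methylated fraction over many fully-methylated sites is within
    3 SE of level/100 at Poisson coverage."""
    cfg = TrioConfig(
        chrom_length=30_000,
        seed=8,
        context_meth_prob={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
        clone_noise_sd=0.0,
        epimutation_rate=0.0,
    )
    truth, meth = simulate_trio(cfg, annotations=False)
    t = meth["CF1"]["CF_c1"]
    cov = (t["count_m"] + t["count_u"]).to_numpy()
    frac = t["count_m"].sum() / cov.sum()
    p = cfg.level_methylated / 100
    se = np.sqrt(p * (1 - p) / cov.sum())
    assert abs(frac - p) < 3 * se
    assert abs(cov.mean() - cfg.mean_coverage) < 3 * np.sqrt(
        cfg.mean_coverage / len(t)
    )


# -- annotations ---------------------------------------------------------


def test_annotations_no_repeats_empty_bed(tmp_path):
    cfg = TrioConfig(chrom_length=20_000, seed=9)
    truth = simulate_trio_genomes(cfg)
    simulate_annotations(
        truth, cfg, n_genes=3, n_repeats=0, intron_te_fraction=0.0, n_gbm=1, n_tem=1
    )
    assert truth.repeats["CF1"].empty
    from panmeth.genes import read_bed, write_bed

    p = tmp_path / "rep.bed"
    write_bed(truth.repeats["CF1"], p)
    assert read_bed(p).empty
    assert p.read_text().startswith("track")


def test_annotations_overflow_rejected():
    cfg = TrioConfig(chrom_length=5_000, seed=9)
    truth = simulate_trio_genomes(cfg)
    with pytest.raises(ValueError, match="cannot place|placed only"):
        simulate_annotations(truth, cfg, n_genes=10)


def test_intron_te_fraction_binomial():
    cfg = TrioConfig(chrom_length=120_000, seed=10)
    truth = simulate_trio_genomes(cfg)
    simulate_annotations(
        truth, cfg, n_genes=50, n_repeats=0, intron_te_fraction=0.8, n_gbm=0, n_tem=0
    )
    reps = truth.repeats["CF1"]
    with_te = reps["name"].str.contains("intron").sum() if len(reps) else 0
    genes_with = reps["name"].str.extract(r"TE_intron_(gene\d+)")[0].nunique()
    # ~ Binomial(100 introns, 0.8) repeats; >=1-intron genes close to 50*(1-0.2^2)
    assert 60 <= with_te <= 95
    assert 35 <= genes_with <= 50


def test_gene_placement_non_overlapping(small_trio):
    _, truth, _ = small_trio
    for hap in ("CF1", "CSSB"):
        genes = truth.genes[hap].sort_values(["chrom", "start"])
        for chrom, sub in genes.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()


# -- single-reference bias -----------------------------------------------


def test_self_mapping_identity(small_trio):
    _, truth, methylomes = small_trio
    hap = "CSCF"
    biased = emit_single_reference_calls(truth, methylomes[hap], hap, hap, seed=1)
    for clone, table in biased.items():
        orig = methylomes[hap][clone]
        merged = orig.merge(table, on=["chrom", "pos", "strand"], suffixes=("", "_b"))
        assert len(merged) == len(orig) == len(table)
        assert (merged["count_m"] == merged["count_m_b"]).all()
        assert (merged["count_u"] == merged["count_u_b"]).all()


def test_ct_snp_emits_unmethylated():
    from panmeth.simulate import refbias_scenario_config

    cfg = refbias_scenario_config(seed=3, chrom_length=20_000)
    truth, meth = simulate_trio(cfg, annotations=False)
    biased = emit_single_reference_calls(truth, meth["CSSB"], "CSSB", "CSCF", seed=3)
    ct = truth.variants[truth.variants["planted_ct"]]
    assert len(ct) > 0
    table = biased[next(iter(biased))].set_index("pos")
    hits = 0
    for _, v in ct.iterrows():
        pos = int(v["pos_CSCF"]) + 1
        if pos in table.index:
            row = table.loc[pos]
            assert int(np.atleast_1d(row["count_m"])[0]) == 0
            hits += 1
    assert hits > 0


def test_sample_deletion_absent_from_reference_calls():
    cfg = TrioConfig(chrom_length=30_000, seed=0, sv_count=4)
    truth, meth = simulate_trio(cfg, annotations=False)
    dels = truth.variants.query("type == 'INDEL' and allele_CSSB == '' and anc_len >= 50")
    assert not dels.empty
    biased = emit_single_reference_calls(truth, meth["CSSB"], "CSSB", "CSCF", seed=1)
    table = biased[next(iter(biased))]
    for _, v in dels.iterrows():
        start = int(v["pos_CSCF"])
        end = start + len(v["allele_CSCF"])
        inside = table[(table["pos"] - 1 >= start) & (table["pos"] - 1 < end)]
        assert inside.empty


def test_unknown_haplotype_rejected(small_trio):
    _, truth, methylomes = small_trio
    with pytest.raises(KeyError):
        emit_single_reference_calls(truth, methylomes["CF1"], "CF1", "nope", seed=0)


# -- outputs -------------------------------------------------------------


def test_write_outputs_round_trip(tmp_path, small_trio):
    cfg, truth, methylomes = small_trio
    outdir = tmp_path / "trio"
    write_outputs(truth, methylomes, str(outdir))
    from panmeth.graph import read_gfa
    from panmeth.methio import read_cx_report

    g = read_gfa(outdir / "graph.chr1.gfa")
    assert path_sequence(g, "CSCF") == truth.haplotype_sequences["CSCF"]["chr1"]
    cx = read_cx_report(outdir / "cx" / "CF1.CF_c1.CX_report.txt")
    pd.testing.assert_frame_equal(
        cx, methylomes["CF1"]["CF_c1"].reset_index(drop=True), check_dtype=False
    )
    assert (outdir / "truth" / "variants.tsv").exists()
    assert (outdir / "config.yaml").exists()
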