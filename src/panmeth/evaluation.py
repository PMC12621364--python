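"""Study-condition evaluations on synthetic trios.

Each function builds a scenario with the generator, runs the relevant
part of the pipeline, and measures how well the known ground truth is
recovered: graph integrity, projection agreement, variant recovery,
null calibration of the differential test, inheritance recovery,
methylation-sharing signal, single-reference bias correction, and gene
classification.  Both the test suite and the reproduction script drive
these; all randomness flows from the ``seed`` arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dma, refbias
from .config import HAPLOTYPES, TrioConfig
from .genes import classify_gene_methylation, genes_from_frames
from .graph import chop_nodes, extract_path_variants, path_sequence, project_position, read_gfa, write_gfa
from .methio import united_profiles
from .nodes import assign_sites_to_nodes
from .simulate import (
    cytosine_sites,
    emit_single_reference_calls,
    inherited_differential_config,
    intra_differential_config,
    null_scenario_config,
    refbias_scenario_config,
    simulate_trio,
    simulate_trio_genomes,
)

__all__ = [
    "evaluate_graph_integrity",
    "evaluate_projection",
    "evaluate_variant_extraction",
    "evaluate_null_calibration",
    "evaluate_inheritance_recovery",
    "evaluate_intra_concordance",
    "evaluate_node_sharing",
    "evaluate_refbias",
    "evaluate_gene_classification",
]

_COMPARISONS = ("CSvSB", "CFvSB", "CSvCF", "SBvCF")


def _standard_pipeline(truth, methylomes, thresholds=None):
    """Unite clones, chop, window, and test the four cultivar comparisons."""
    thresholds = thresholds or dma.DMAThresholds()
    profiles = united_profiles(methylomes)
    all_windows: list = []
    frames = []
    for chrom in truth.chroms:
        graph, _ = chop_nodes(truth.graphs[chrom], 200)
        windows, _ = dma.build_windows(graph, profiles, thresholds)
        all_windows.extend(windows)
        for comp in _COMPARISONS:
            frames.append(dma.run_comparison(windows, profiles, comp, chrom=chrom))
    called = dma.adjust_and_call(pd.concat(frames, ignore_index=True), thresholds)
    return profiles, all_windows, called


def evaluate_graph_integrity(
    seed: int, n_trios: int = 50, chrom_length: int = 50_000, n_chromosomes: int = 2,
    tmpdir: str | None = None,
) -> dict:
    """Chop preservation and GFA round-trip identity over random trios."""
    import os
    import tempfile

    paths_total = paths_ok = roundtrip_ok = 0
    for k in range(n_trios):
        cfg = TrioConfig(
            chrom_length=chrom_length, n_chromosomes=n_chromosomes, seed=seed + k
        )
        truth = simulate_trio_genomes(cfg)
        for chrom, graph in truth.graphs.items():
            chopped, _ = chop_nodes(graph, 200)
            for hap in HAPLOTYPES:
                paths_total += 1
                if (
                    path_sequence(chopped, hap)
                    == truth.haplotype_sequences[hap][chrom]
                ):
                    paths_ok += 1
            with tempfile.TemporaryDirectory(dir=tmpdir) as d:
                f = os.path.join(d, "g.gfa")
                write_gfa(chopped, f)
                back = read_gfa(f)
            if (
                back.nodes == chopped.nodes
                and back.paths == chopped.paths
                and back.edges == chopped.edges
            ):
                roundtrip_ok += 1
    return {
        "path_preservation_rate": paths_ok / paths_total,
        "gfa_roundtrip_rate": roundtrip_ok / (n_trios * n_chromosomes),
        "n_paths": paths_total,
    }


def evaluate_projection(seed: int, n_samples: int = 10_000) -> dict:
    """Projection vs the generator's truth coordinate maps, plus the
    none-at-private-allele convention."""
    cfg = TrioConfig(chrom_length=60_000, seed=seed)
    truth = simulate_trio_genomes(cfg)
    graph = truth.graphs["chr1"]
    rng = np.random.default_rng(seed)
    pairs = [("CF1", "SB1"), ("CF2", "CSSB"), ("CSCF", "SB2"), ("CSCF", "CSSB")]
    per_pair = max(1, n_samples // len(pairs))
    agree = total = 0
    for hap_a, hap_b in pairs:
        pa, pb = truth.coordinate_map(hap_a, hap_b, "chr1")
        idx = rng.integers(0, len(pa), per_pair)
        for i in idx:
            total += 1
            if project_position(graph, hap_a, int(pa[i]), hap_b) == pb[i]:
                agree += 1
    # positions inside a differing allele must not project
    private_none = private_total = 0
    vt = truth.variants
    for _, v in vt[vt["allele_CF1"] != vt["allele_SB1"]].head(500).iterrows():
        if not v["allele_CF1"]:
            continue
        private_total += 1
        if project_position(graph, "CF1", int(v["pos_CF1"]), "SB1") is None:
            private_none += 1
    return {
        "agreement_rate": agree / total,
        "n_sampled": total,
        "private_none_rate": private_none / max(private_total, 1),
    }


def evaluate_variant_extraction(seed: int, chrom_length: int = 60_000) -> dict:
    """Recovery of simulated non-adjacent variants with exact alleles,
    and SV flagging of large indels."""
    cfg = TrioConfig(chrom_length=chrom_length, seed=seed, sv_count=8)
    truth = simulate_trio_genomes(cfg)
    graph = truth.graphs["chr1"]
    hit = total = sv_total = sv_flagged = 0
    for hap_a, hap_b in (("CF1", "SB1"), ("CF2", "SB2"), ("CSCF", "CSSB")):
        found = {
            (v.pos_a, v.allele_a, v.allele_b)
            for v in extract_path_variants(graph, hap_a, hap_b)
        }
        sv_found = {
            (v.pos_a, v.allele_a, v.allele_b)
            for v in extract_path_variants(graph, hap_a, hap_b)
            if v.is_sv
        }
        vt = truth.variants.sort_values("anc_pos")
        differs = vt[vt[f"allele_{hap_a}"] != vt[f"allele_{hap_b}"]]
        starts = differs["anc_pos"].to_numpy()
        ends = starts + differs["anc_len"].to_numpy()
        nonadj = np.ones(len(differs), dtype=bool)
        if len(differs) > 1:
            nonadj[1:] &= starts[1:] > ends[:-1]
            nonadj[:-1] &= starts[1:] > ends[:-1]
        for (_, v), na in zip(differs.iterrows(), nonadj):
            key = (v[f"pos_{hap_a}"], v[f"allele_{hap_a}"], v[f"allele_{hap_b}"])
            if na:
                total += 1
                hit += key in found
            if v["is_sv"] and na:
                sv_total += 1
                sv_flagged += key in sv_found
    return {
        "recovery_rate": hit / total,
        "n_nonadjacent": total,
        "sv_flag_rate": sv_flagged / max(sv_total, 1),
        "n_svs": sv_total,
    }


def evaluate_null_calibration(seed: int, chrom_length: int = 450_000) -> dict:
    """Fraction of window tests reaching q < 0.01 when no differential
    exists anywhere (identical methylation states, no epimutation)."""
    cfg = null_scenario_config(seed, chrom_length)
    truth, methylomes = simulate_trio(cfg, annotations=False)
    _, windows, called = _standard_pipeline(truth, methylomes)
    return {
        "call_fraction": float((called["q_value"] < 0.01).mean()),
        "n_windows": len(windows),
        "n_tests": len(called),
    }


def _truth_window_cg_diff(truth, windows, group_a, group_b):
    """Truth CG-level differential per window from the simulated states."""
    levels = {}
    for hap in group_a + group_b:
        st = truth.site_states[hap]
        st = st[st["context"] == "CG"]
        levels[hap] = (
            np.sort(st["pos"].to_numpy() - 1),
            st["level"].to_numpy()[np.argsort(st["pos"].to_numpy() - 1, kind="stable")],
        )

    def mean_level(hap, s, e):
        pos, lvl = levels[hap]
        lo, hi = np.searchsorted(pos, (s, e))
        return lvl[lo:hi].mean() if hi > lo else np.nan

    rows = []
    for w in windows:
        la = np.nanmean([mean_level(h, *w.intervals[h]) for h in group_a])
        lb = np.nanmean([mean_level(h, *w.intervals[h]) for h in group_b])
        rows.append({"window_id": w.window_id, "truth_diff": la - lb})
    return pd.DataFrame(rows)


def evaluate_inheritance_recovery(
    seed: int, chrom_length: int = 100_000, truth_diff_min: float = 70.0
) -> dict:
    """Planted parental CG differential: fraction of truth windows called
    as DMRs and assigned to an inherited set."""
    cfg = inherited_differential_config(seed, chrom_length)
    truth, methylomes = simulate_trio(cfg, annotations=False)
    _, windows, called = _standard_pipeline(truth, methylomes)
    tw = _truth_window_cg_diff(truth, windows, ["CF1", "CF2"], ["SB1", "SB2"])
    truth_ids = set(tw[tw["truth_diff"] >= truth_diff_min]["window_id"])
    cg = called[(called["comparison"] == "CFvSB") & (called["context"] == "CG")]
    hit = cg[cg["window_id"].isin(truth_ids)]
    recall = float((hit["call"] != "ns").mean()) if len(hit) else float("nan")
    sets_ = dma.inherited_dmr_sets(called)
    inherited_ids = set(
        sets_["iCF"].query("context == 'CG'")["window_id"]
    ) | set(sets_["iSB"].query("context == 'CG'")["window_id"])
    assigned = (
        len(truth_ids & inherited_ids) / len(truth_ids) if truth_ids else float("nan")
    )
    return {
        "dmr_recall": recall,
        "inherited_assignment": assigned,
        "n_truth_windows": len(truth_ids),
    }


def evaluate_intra_concordance(seed: int, chrom_length: int = 100_000) -> dict:
    """Within-parent differential with zero epimutation: the hybrid must
    match at least one parental haplotype on almost every intra DMR."""
    cfg = intra_differential_config(seed, chrom_length)
    truth, methylomes = simulate_trio(cfg, annotations=False)
    profiles = united_profiles(methylomes)
    thresholds = dma.DMAThresholds()
    graph, _ = chop_nodes(truth.graphs["chr1"], 200)
    windows, _ = dma.build_windows(graph, profiles, thresholds)
    fracs, weights = [], []
    for h1, h2, cs_hap in (("CF1", "CF2", "CSCF"), ("SB1", "SB2", "CSSB")):
        res = dma.run_comparison(
            windows, profiles, f"{h1}:{h2}", chrom="chr1", groups={h1: [h1], h2: [h2]}
        )
        called = dma.adjust_and_call(res, thresholds)
        cs_levels = pd.concat(
            [
                dma.window_levels(windows, profiles, [cs_hap], ctx, chrom="chr1")
                for ctx in ("CG", "CHG", "CHH")
            ],
            ignore_index=True,
        )
        frac, records = dma.intra_cultivar_concordance(called, cs_levels, thresholds)
        if len(records):
            fracs.append(frac)
            weights.append(len(records))
    overall = float(np.average(fracs, weights=weights)) if fracs else float("nan")
    return {"concordance": overall, "n_dmrs": int(sum(weights))}


def evaluate_node_sharing(
    seed: int, n_replicates: int = 20, chrom_length: int = 30_000
) -> dict:
    """Methylation-aware node sharing: progeny vs source parental
    haplotype beats the two haplotypes of that parent."""
    wins = 0
    for k in range(n_replicates):
        cfg = TrioConfig(chrom_length=chrom_length, seed=seed + k, epimutation_rate=0.01)
        truth, methylomes = simulate_trio(cfg, annotations=False)
        profiles = united_profiles(methylomes)
        graph, _ = chop_nodes(truth.graphs["chr1"], 200)
        matrix = assign_sites_to_nodes(graph, profiles)
        src = truth.inheritance["chr1"]["CSCF"][0][2]
        shared_pc = sum(
            1
            for n in matrix.presence
            if matrix.methylated(n, src) and matrix.methylated(n, "CSCF")
        )
        shared_pp = sum(
            1
            for n in matrix.presence
            if matrix.methylated(n, "CF1") and matrix.methylated(n, "CF2")
        )
        wins += shared_pc > shared_pp
    return {"win_fraction": wins / n_replicates, "n_replicates": n_replicates}


def evaluate_refbias(seed: int, chrom_length: int = 100_000) -> dict:
    """Bias correction: recovery of truly-methylated biased regions,
    exactness of the per-site porting, and C>T enrichment.

    A region counts as a truly-methylated biased region when the
    sample's true level is >= 75% and the planted C>T substitutions are
    expected to depress the single-reference estimate by at least the
    20-point delta threshold of the grouping."""
    cfg = refbias_scenario_config(seed, chrom_length)
    truth, methylomes = simulate_trio(cfg, annotations=False)
    sample_hap, reference_hap = "CSSB", "CSCF"
    biased = emit_single_reference_calls(
        truth, methylomes[sample_hap], sample_hap, reference_hap, seed=seed
    )
    graph, _ = chop_nodes(truth.graphs["chr1"], 200)
    chunks = refbias.homologous_chunks(graph, reference_hap, sample_hap)
    records, ported = refbias.port_methylation(
        biased, methylomes[sample_hap], chunks, graph=graph, chrom="chr1"
    )
    grouped = refbias.classify_correction_groups(
        records[records["context"] == "all"]
    )

    st = truth.site_states[sample_hap]
    spos = st["pos"].to_numpy() - 1
    slvl = st["level"].to_numpy()
    ref_sites = cytosine_sites(truth.haplotype_sequences[reference_hap]["chr1"])
    rpos = ref_sites["pos0"].to_numpy()
    ct = truth.variants[truth.variants["planted_ct"]]
    ctpos = np.sort(ct["pos_CSCF"].to_numpy())
    corrected = total = 0
    for _, r in grouped.iterrows():
        sel_lo, sel_hi = np.searchsorted(spos, (r["alt_start"], r["alt_end"]))
        if sel_hi <= sel_lo:
            continue
        truth_level = slvl[sel_lo:sel_hi].mean()
        n_ref = np.searchsorted(rpos, r["ref_end"]) - np.searchsorted(rpos, r["ref_start"])
        n_hidden = np.searchsorted(ctpos, r["ref_end"]) - np.searchsorted(ctpos, r["ref_start"])
        if n_ref == 0:
            continue
        depression = truth_level * n_hidden / n_ref
        if truth_level >= 75.0 and depression >= 20.0:
            total += 1
            corrected += r["group"] == "corrected"

    pooled = refbias._pooled_site_levels(methylomes[sample_hap], "chr1")
    lut = {
        (p, s): lv
        for p, s, lv in zip(pooled["pos0"], pooled["strand"], pooled["level"])
    }
    err = np.array(
        [
            abs(row["level"] - lut[(row["alt_pos0"], row["strand"])])
            for _, row in ported.iterrows()
        ]
    )
    variants = extract_path_variants(graph, reference_hap, sample_hap)
    _, fisher = refbias.substitution_enrichment(grouped, variants)
    return {
        "corrected_recall": corrected / max(total, 1),
        "n_biased_regions": total,
        "ported_within_5pp": float((err <= 5.0).mean()),
        "n_ported_sites": len(err),
        "ct_fisher_p": fisher["p_value"],
        "ct_odds_ratio": fisher["odds_ratio"],
    }


def evaluate_gene_classification(
    seed: int, n_genes: int = 100, chrom_length: int = 250_000
) -> dict:
    """Forced gbM/teM genes recover their labels from 30x clone data."""
    cfg = TrioConfig(chrom_length=chrom_length, seed=seed)
    truth, methylomes = simulate_trio(
        cfg, n_genes=n_genes, n_gbm=n_genes * 3 // 10, n_tem=n_genes * 3 // 10
    )
    hap = "CF1"
    profile = united_profiles({hap: methylomes[hap]})[hap]
    models = genes_from_frames(truth.genes[hap], truth.exons[hap])
    cls = classify_gene_methylation(models, profile)
    merged = cls.merge(truth.gene_classes, on="gene_id")
    forced = merged[merged["forced_class"] != "none"]
    accuracy = float((forced["meth_class"] == forced["forced_class"]).mean())
    return {
        "forced_accuracy": accuracy,
        "n_forced": len(forced),
        "classes": merged,
        "profile": profile,
        "models": models,
    }
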