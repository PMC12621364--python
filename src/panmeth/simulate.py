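"""Synthetic parent-progeny trio generator with full ground truth.

Emulates the data structure of a hybrid-trio bisulfite study: an ancestral
chromosome is mutated independently into the four parental haplotypes
(CF1/CF2 and SB1/SB2); the progeny CS copies one haplotype of each parent
(CSCF and CSSB).  The variation graph is built directly from the known
variant table — shared ancestral segments become shared nodes, alternate
alleles become branch nodes — so every cross-haplotype coordinate
relation is known exactly and can serve as an oracle for graph
projection, variant extraction, differential methylation, and
single-reference bias correction.

Methylomes are two-level mixtures: each cytosine (or each ancestral
block) is in a methylated state (level ``level_methylated``) or an
unmethylated state (``level_unmethylated``); CS sites inherit the state
of the copied parental haplotype, flipped with the epimutation
probability; clones add Gaussian level noise and binomial count noise at
Poisson coverage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CONTEXTS,
    CULTIVAR_OF,
    HAPLOTYPES,
    PARENTAL_HAPLOTYPES,
    TrioConfig,
)
from .graph import SequenceGraph, _infer_edges, write_gfa

__all__ = [
    "TrioTruth",
    "simulate_trio_genomes",
    "simulate_annotations",
    "simulate_methylomes",
    "simulate_trio",
    "emit_single_reference_calls",
    "cytosine_sites",
    "write_outputs",
    "null_scenario_config",
    "inherited_differential_config",
    "intra_differential_config",
    "refbias_scenario_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[_b] = _i
_C, _G, _A, _T = ord("C"), ord("G"), ord("A"), ord("T")
_COMP = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP[_x] = _y


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------


@dataclass
class TrioTruth:
    """Everything the generator knows: sequences, graph, coordinates, states.

    Haplotype/graph coordinates are 0-based; site tables use 1-based
    positions (CX-report convention).
    """

    config: TrioConfig
    chroms: list[str] = field(default_factory=list)
    graphs: dict[str, SequenceGraph] = field(default_factory=dict)
    haplotype_sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    variants: pd.DataFrame | None = None
    # per haplotype, per chromosome: ancestral coordinate of each base
    # (-1 for inserted/alternate bases)
    anc_of: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    # per haplotype, per chromosome: haplotype position of each ancestral
    # base carried by this haplotype (-1 where deleted/substituted)
    pos_at_anc: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    # like pos_at_anc/anc_of but also covering equal-length substituted
    # alleles (SNP/MNP): positionally aligned, base may differ.  Used to
    # emulate read mapping onto a diverged linear reference.
    aligned_pos_at_anc: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    aligned_anc_of: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def hap_alignment(self, hap_a: str, hap_b: str, chrom: str) -> np.ndarray:
        """Positional alignment a -> b (base-level, -1 where unaligned).

        Aligned bases are shared ancestral segments, identical alleles,
        and equal-length substituted alleles (whose bases may differ) —
        the positions a read mapper would place on either haplotype.
        """
        len_a = len(self.haplotype_sequences[hap_a][chrom])
        out = np.full(len_a, -1, dtype=np.int64)
        variants = self.variants[self.variants["chrom"] == chrom]
        cur_a = cur_b = 0
        for _, v in variants.sort_values("anc_pos").iterrows():
            pa, pb = int(v[f"pos_{hap_a}"]), int(v[f"pos_{hap_b}"])
            seg = pa - cur_a
            assert seg == pb - cur_b
            if seg > 0:
                out[cur_a : cur_a + seg] = np.arange(cur_b, cur_b + seg)
            aa, ab = v[f"allele_{hap_a}"], v[f"allele_{hap_b}"]
            aa = "" if pd.isna(aa) else str(aa)
            ab = "" if pd.isna(ab) else str(ab)
            if len(aa) == len(ab) and len(aa) > 0:
                out[pa : pa + len(aa)] = np.arange(pb, pb + len(ab))
            cur_a, cur_b = pa + len(aa), pb + len(ab)
        tail = len_a - cur_a
        if tail > 0:
            out[cur_a:] = np.arange(cur_b, cur_b + tail)
        return out
    # per chromosome: list of (anc_start, anc_end, source_hap) per CS hap
    inheritance: dict[str, dict[str, list[tuple[int, int, str]]]] = field(
        default_factory=dict
    )
    # ancestral-block methylation states (bias scenario) per chromosome
    block_states: dict[str, np.ndarray] = field(default_factory=dict)
    # planted differential blocks per chromosome: (anc_start, anc_end)
    planted_blocks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    # per haplotype: site-state table (chrom, pos, strand, context,
    # trinuc, state, level) filled by simulate_methylomes
    site_states: dict[str, pd.DataFrame] = field(default_factory=dict)
    # annotations (ancestral coordinates + per-haplotype lifts)
    genes: dict[str, pd.DataFrame] = field(default_factory=dict)
    exons: dict[str, pd.DataFrame] = field(default_factory=dict)
    repeats: dict[str, pd.DataFrame] = field(default_factory=dict)
    gene_classes: pd.DataFrame | None = None

    def coordinate_map(
        self, hap_a: str, hap_b: str, chrom: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Paired positions of homologous (ancestral) bases on two haplotypes."""
        pa = self.pos_at_anc[hap_a][chrom]
        pb = self.pos_at_anc[hap_b][chrom]
        mask = (pa >= 0) & (pb >= 0)
        return pa[mask], pb[mask]

    def source_of(self, cs_hap: str, chrom: str, anc_pos: int) -> str:
        for start, end, src in self.inheritance[chrom][cs_hap]:
            if start <= anc_pos < end:
                return src
        raise ValueError(f"ancestral position {anc_pos} outside {chrom}")


# ---------------------------------------------------------------------------
# genomes and graph
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _draw_events(
    rng: np.random.Generator,
    anc: np.ndarray,
    config: TrioConfig,
    block_states: np.ndarray | None,
) -> list[dict]:
    """Draw SNP/indel/SV events with per-haplotype alternate alleles."""
    L = len(anc)
    events: dict[int, dict] = {}

    def _event(pos: int, anc_len: int, vtype: str) -> dict:
        return events.setdefault(
            pos,
            {
                "anc_start": pos,
                "anc_end": pos + anc_len,
                "type": vtype,
                "alleles": {},
                "planted_ct": False,
            },
        )

    # SNPs, drawn independently per parental haplotype
    for hap in PARENTAL_HAPLOTYPES:
        hits = np.flatnonzero(rng.random(L) < config.snp_rate)
        offsets = rng.integers(1, 4, size=hits.size)  # 1..3 steps from ref
        for pos, off in zip(hits.tolist(), offsets.tolist()):
            alt = chr(_BASES[(_BASE_INDEX[anc[pos]] + off) % 4])
            ev = _event(pos, 1, "SNP")
            if ev["type"] == "SNP":
                ev["alleles"][hap] = alt

    # planted C>T (G>A) transitions on the SB lineage inside methylated
    # ancestral blocks (single-reference bias scenario)
    if config.ct_snp_fraction > 0 and block_states is not None:
        bs = config.state_block_bp or 200
        is_cg = (anc == _C) | (anc == _G)
        blocks = np.arange(L) // bs
        meth = block_states[blocks] > 0
        hits = np.flatnonzero(is_cg & meth & (rng.random(L) < config.ct_snp_fraction))
        for pos in hits.tolist():
            ev = _event(pos, 1, "SNP")
            if ev["type"] != "SNP":
                continue
            alt = "T" if anc[pos] == _C else "A"
            ev["alleles"]["SB1"] = alt
            ev["alleles"]["SB2"] = alt
            ev["planted_ct"] = True

    # small indels, one owner haplotype each
    for hap in PARENTAL_HAPLOTYPES:
        hits = np.flatnonzero(rng.random(L) < config.indel_rate)
        for pos in hits.tolist():
            length = int(min(rng.geometric(0.35), 10))
            if rng.random() < 0.5 and pos + length < L - 1:  # deletion
                ev = _event(pos, length, "INDEL")
                if ev["type"] == "INDEL" and ev["anc_end"] == pos + length:
                    ev["alleles"].setdefault(hap, "")
            else:  # insertion before base pos
                ins = _random_sequence(rng, length, config.gc_content)
                ev = _event(pos, 0, "INDEL")
                if ev["type"] == "INDEL" and ev["anc_end"] == pos:
                    ev["alleles"].setdefault(hap, ins.tobytes().decode())

    # structural variants (indels >= 50 bp)
    for _ in range(config.sv_count):
        hap = PARENTAL_HAPLOTYPES[int(rng.integers(0, 4))]
        length = int(rng.integers(50, 151))
        pos = int(rng.integers(1, L - length - 1))
        if rng.random() < 0.5:
            ev = _event(pos, length, "INDEL")
            if ev["type"] == "INDEL" and ev["anc_end"] == pos + length:
                ev["alleles"].setdefault(hap, "")
        else:
            ins = _random_sequence(rng, length, config.gc_content)
            ev = _event(pos, 0, "INDEL")
            if ev["type"] == "INDEL" and ev["anc_end"] == pos:
                ev["alleles"].setdefault(hap, ins.tobytes().decode())

    # greedy conflict resolution: keep non-overlapping events, leave the
    # terminal bases shared so every path starts/ends on an anchor node
    kept: list[dict] = []
    prev_end = 1
    for pos in sorted(events):
        ev = events[pos]
        if not ev["alleles"]:
            continue
        if ev["anc_start"] < prev_end or ev["anc_end"] > len(anc) - 1:
            continue
        ev["ref"] = anc[ev["anc_start"] : ev["anc_end"]].tobytes().decode()
        kept.append(ev)
        prev_end = max(ev["anc_end"], ev["anc_start"] + 1)
    return kept


def _inheritance_segments(
    rng: np.random.Generator, L: int, haps: tuple[str, str], n_breaks: int
) -> list[tuple[int, int, str]]:
    first = int(rng.integers(0, 2))
    if n_breaks <= 0:
        return [(0, L, haps[first])]
    breaks = sorted(int(b) for b in rng.integers(1, L, size=n_breaks))
    bounds = [0, *breaks, L]
    return [
        (bounds[i], bounds[i + 1], haps[(first + i) % 2])
        for i in range(len(bounds) - 1)
    ]


def simulate_trio_genomes(config: TrioConfig) -> TrioTruth:
    """Mutate an ancestral sequence into six haplotypes and build the graph.

    Raises ``ValueError`` when the expected variant spacing is below 2 bp
    (the bubble graph would degenerate).
    """
    total_rate = 4 * (config.snp_rate + config.indel_rate) + config.ct_snp_fraction
    if total_rate > 0 and 1.0 / total_rate < 2.0:
        raise ValueError(
            f"expected variant spacing {1.0 / total_rate:.2f} bp < 2 bp; "
            "lower snp_rate/indel_rate"
        )

    truth = TrioTruth(config=config)
    truth.chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for hap in HAPLOTYPES:
        truth.haplotype_sequences[hap] = {}
        truth.anc_of[hap] = {}
        truth.pos_at_anc[hap] = {}
        truth.aligned_anc_of[hap] = {}
        truth.aligned_pos_at_anc[hap] = {}
    var_rows: list[dict] = []

    for ci, chrom in enumerate(truth.chroms):
        rng = np.random.default_rng([config.seed, 11, ci])
        L = config.chrom_length
        anc = _random_sequence(rng, L, config.gc_content)

        block_states = None
        if config.ancestral_block_states:
            bs = config.state_block_bp or 200
            n_blocks = (L + bs - 1) // bs
            p_block = config.context_meth_prob.get("CG", 0.5)
            block_states = (rng.random(n_blocks) < p_block).astype(np.int8)
            truth.block_states[chrom] = block_states

        events = _draw_events(rng, anc, config, block_states)

        truth.inheritance[chrom] = {
            "CSCF": _inheritance_segments(
                rng, L, ("CF1", "CF2"), config.recombination_breakpoints
            ),
            "CSSB": _inheritance_segments(
                rng, L, ("SB1", "SB2"), config.recombination_breakpoints
            ),
        }

        # resolve CS alleles from the inherited parental haplotype
        for ev in events:
            for cs_hap in ("CSCF", "CSSB"):
                src = truth.source_of(cs_hap, chrom, ev["anc_start"])
                if src in ev["alleles"]:
                    ev["alleles"][cs_hap] = ev["alleles"][src]

        graph, per_hap = _build_graph_and_sequences(anc, events, chrom)
        truth.graphs[chrom] = graph
        for hap in HAPLOTYPES:
            seq, anc_of, pos_at_anc, al_anc_of, al_pos_at_anc = per_hap[hap]
            truth.haplotype_sequences[hap][chrom] = seq
            truth.anc_of[hap][chrom] = anc_of
            truth.pos_at_anc[hap][chrom] = pos_at_anc
            truth.aligned_anc_of[hap][chrom] = al_anc_of
            truth.aligned_pos_at_anc[hap][chrom] = al_pos_at_anc

        for ev in events:
            row = {
                "chrom": chrom,
                "anc_pos": ev["anc_start"],
                "anc_len": ev["anc_end"] - ev["anc_start"],
                "ref": ev["ref"],
                "type": ev["type"],
                "planted_ct": ev["planted_ct"],
            }
            ref_len = row["anc_len"]
            max_diff = 0
            for hap in HAPLOTYPES:
                allele = ev["alleles"].get(hap, ev["ref"])
                row[f"allele_{hap}"] = allele
                row[f"pos_{hap}"] = ev["hap_pos"][hap]
                max_diff = max(max_diff, abs(len(allele) - ref_len))
            row["length"] = max_diff if ev["type"] == "INDEL" else ref_len
            row["is_sv"] = ev["type"] == "INDEL" and row["length"] >= 50
            var_rows.append(row)

    truth.variants = pd.DataFrame(var_rows)
    return truth


def _build_graph_and_sequences(
    anc: np.ndarray, events: list[dict], chrom: str
) -> tuple[SequenceGraph, dict]:
    """Bubble graph from the variant table; one allele node per distinct allele."""
    graph = SequenceGraph(name=chrom)
    paths: dict[str, list[tuple[str, str]]] = {h: [] for h in HAPLOTYPES}
    seq_parts: dict[str, list[str]] = {h: [] for h in HAPLOTYPES}
    # (anc_start, anc_end, hap_start) runs of reference-carried bases
    ref_runs: dict[str, list[tuple[int, int, int]]] = {h: [] for h in HAPLOTYPES}
    # additionally: equal-length substituted alleles (aligned positions)
    sub_runs: dict[str, list[tuple[int, int, int]]] = {h: [] for h in HAPLOTYPES}
    hap_len: dict[str, int] = {h: 0 for h in HAPLOTYPES}
    next_id = 1

    def _add_node(seq: str) -> str:
        nonlocal next_id
        nid = str(next_id)
        next_id += 1
        graph.nodes[nid] = seq
        return nid

    def _shared_segment(a0: int, a1: int) -> None:
        if a1 <= a0:
            return
        seq = anc[a0:a1].tobytes().decode()
        nid = _add_node(seq)
        for h in HAPLOTYPES:
            paths[h].append((nid, "+"))
            seq_parts[h].append(seq)
            ref_runs[h].append((a0, a1, hap_len[h]))
            hap_len[h] += a1 - a0

    cursor = 0
    for ev in events:
        _shared_segment(cursor, ev["anc_start"])
        ev["hap_pos"] = {h: hap_len[h] for h in HAPLOTYPES}
        groups: dict[str, list[str]] = {}
        for h in HAPLOTYPES:
            allele = ev["alleles"].get(h, ev["ref"])
            groups.setdefault(allele, []).append(h)
        for allele, members in groups.items():
            if not allele:
                continue  # deletion allele: path skips the site
            nid = _add_node(allele)
            span = ev["anc_end"] - ev["anc_start"]
            is_ref = allele == ev["ref"] and span > 0
            is_sub = not is_ref and span > 0 and len(allele) == span
            for h in members:
                paths[h].append((nid, "+"))
                seq_parts[h].append(allele)
                if is_ref:
                    ref_runs[h].append((ev["anc_start"], ev["anc_end"], hap_len[h]))
                elif is_sub:
                    sub_runs[h].append((ev["anc_start"], ev["anc_end"], hap_len[h]))
                hap_len[h] += len(allele)
        cursor = ev["anc_end"]
    _shared_segment(cursor, len(anc))

    graph.paths = paths
    _infer_edges(graph)

    per_hap = {}
    L = len(anc)
    for h in HAPLOTYPES:
        seq = "".join(seq_parts[h])
        anc_of = np.full(hap_len[h], -1, dtype=np.int64)
        pos_at_anc = np.full(L, -1, dtype=np.int64)
        for a0, a1, h0 in ref_runs[h]:
            n = a1 - a0
            anc_of[h0 : h0 + n] = np.arange(a0, a1)
            pos_at_anc[a0:a1] = np.arange(h0, h0 + n)
        al_anc_of = anc_of.copy()
        al_pos_at_anc = pos_at_anc.copy()
        for a0, a1, h0 in sub_runs[h]:
            n = a1 - a0
            al_anc_of[h0 : h0 + n] = np.arange(a0, a1)
            al_pos_at_anc[a0:a1] = np.arange(h0, h0 + n)
        per_hap[h] = (seq, anc_of, pos_at_anc, al_anc_of, al_pos_at_anc)
    return graph, per_hap


# ---------------------------------------------------------------------------
# cytosine sites
# ---------------------------------------------------------------------------


def cytosine_sites(seq: str) -> pd.DataFrame:
    """All cytosines on both strands with trinucleotide context.

    Returns 0-based ``pos0``, ``strand`` (+/-), ``context`` (CG/CHG/CHH)
    and ``trinuc``.  Context is read 5'->3' on the cytosine's strand; N in
    the two downstream bases is treated as H.
    """
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(b)
    pad = np.full(2, ord("N"), dtype=np.uint8)
    nxt1 = np.concatenate([b[1:], pad[:1]])
    nxt2 = np.concatenate([b[2:], pad])
    prv1 = np.concatenate([pad[:1], b[:-1]])
    prv2 = np.concatenate([pad, b[:-2]])

    frames = []
    pos_c = np.flatnonzero(b == _C)
    if pos_c.size:
        ctx = np.where(
            nxt1[pos_c] == _G, "CG", np.where(nxt2[pos_c] == _G, "CHG", "CHH")
        )
        tri = np.stack([b[pos_c], nxt1[pos_c], nxt2[pos_c]], axis=1)
        frames.append((pos_c, "+", ctx, tri))
    pos_g = np.flatnonzero(b == _G)
    if pos_g.size:
        ctx = np.where(
            prv1[pos_g] == _C, "CG", np.where(prv2[pos_g] == _C, "CHG", "CHH")
        )
        tri = np.stack(
            [_COMP[b[pos_g]], _COMP[prv1[pos_g]], _COMP[prv2[pos_g]]], axis=1
        )
        frames.append((pos_g, "-", ctx, tri))

    dfs = []
    for pos, strand, ctx, tri in frames:
        trinuc = tri.astype(np.uint8).tobytes().decode()
        trinucs = [trinuc[i : i + 3] for i in range(0, len(trinuc), 3)]
        dfs.append(
            pd.DataFrame(
                {
                    "pos0": pos,
                    "strand": strand,
                    "context": ctx,
                    "trinuc": trinucs,
                }
            )
        )
    if not dfs:
        return pd.DataFrame(columns=["pos0", "strand", "context", "trinuc"])
    out = pd.concat(dfs, ignore_index=True)
    return out.sort_values(["pos0", "strand"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def simulate_annotations(
    truth: TrioTruth,
    config: TrioConfig,
    n_genes: int = 12,
    exons_per_gene: int = 3,
    exon_len: int = 300,
    intron_len: int = 200,
    n_repeats: int = 10,
    repeat_len: int = 300,
    intron_te_fraction: float = 0.3,
    n_gbm: int = 2,
    n_tem: int = 2,
) -> None:
    """Place non-overlapping multi-exon genes and repeats on the ancestral
    axis and lift them onto every haplotype.

    A subset of genes is forced into gbM (exonic CG methylated, CHG/CHH
    unmethylated) or teM (all contexts methylated in exons); the truth
    labels are recorded in ``truth.gene_classes``.  Raises ``ValueError``
    when the requested genes cannot be placed without overlap.
    """
    rng = np.random.default_rng([config.seed, 23])
    L = config.chrom_length
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    genes_anc: list[dict] = []
    exons_anc: list[dict] = []
    repeats_anc: list[dict] = []

    per_chrom = (n_genes + len(truth.chroms) - 1) // len(truth.chroms)
    gid = 0
    for chrom in truth.chroms:
        n_here = min(per_chrom, n_genes - gid)
        if n_here <= 0:
            break
        margin = 200
        need = n_here * gene_span + (n_here + 1) * margin
        if need > L:
            raise ValueError(
                f"cannot place {n_here} genes of span {gene_span} bp on a "
                f"{L} bp chromosome without overlap"
            )
        slack = L - need
        gaps = rng.multinomial(slack, np.ones(n_here + 1) / (n_here + 1))
        cursor = 0
        for k in range(n_here):
            cursor += margin + int(gaps[k])
            start = cursor
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene{gid + 1:04d}"
            genes_anc.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_span,
                    "strand": strand,
                }
            )
            off = start
            for e in range(exons_per_gene):
                exons_anc.append(
                    {
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "start": off,
                        "end": off + exon_len,
                    }
                )
                off += exon_len
                if e < exons_per_gene - 1:
                    if rng.random() < intron_te_fraction:
                        rl = min(repeat_len, intron_len - 20)
                        r0 = off + int(rng.integers(0, intron_len - rl))
                        repeats_anc.append(
                            {
                                "chrom": chrom,
                                "start": r0,
                                "end": r0 + rl,
                                "name": f"TE_intron_{gene_id}_{e}",
                            }
                        )
                    off += intron_len
            cursor = start + gene_span
            gid += 1
    if gid < n_genes:
        raise ValueError(f"placed only {gid}/{n_genes} genes")

    # intergenic repeats: uniform positions re-drawn until clear of genes
    gene_iv = {
        c: [(g["start"], g["end"]) for g in genes_anc if g["chrom"] == c]
        for c in truth.chroms
    }
    placed = 0
    attempts = 0
    while placed < n_repeats and attempts < 100 * max(n_repeats, 1):
        attempts += 1
        chrom = truth.chroms[int(rng.integers(0, len(truth.chroms)))]
        r0 = int(rng.integers(0, L - repeat_len))
        if any(r0 < e and r0 + repeat_len > s for s, e in gene_iv[chrom]):
            continue
        repeats_anc.append(
            {
                "chrom": chrom,
                "start": r0,
                "end": r0 + repeat_len,
                "name": f"TE_intergenic_{placed + 1}",
            }
        )
        placed += 1

    # forced methylation classes
    order = rng.permutation(len(genes_anc))
    classes = {}
    for i, gi in enumerate(order.tolist()):
        if i < n_gbm:
            classes[genes_anc[gi]["gene_id"]] = "gbM"
        elif i < n_gbm + n_tem:
            classes[genes_anc[gi]["gene_id"]] = "teM"
    truth.gene_classes = pd.DataFrame(
        {
            "gene_id": [g["gene_id"] for g in genes_anc],
            "forced_class": [
                classes.get(g["gene_id"], "none") for g in genes_anc
            ],
        }
    )

    # lift onto every haplotype through the ancestral coordinate map
    for hap in HAPLOTYPES:
        truth.genes[hap] = _lift_frame(truth, hap, pd.DataFrame(genes_anc))
        truth.exons[hap] = _lift_frame(truth, hap, pd.DataFrame(exons_anc))
        truth.repeats[hap] = _lift_frame(truth, hap, pd.DataFrame(repeats_anc))


def _lift_frame(truth: TrioTruth, hap: str, frame: pd.DataFrame) -> pd.DataFrame:
    """Map ancestral [start,end) intervals to haplotype coordinates."""
    if frame.empty:
        return frame.assign(start=pd.Series(dtype=int), end=pd.Series(dtype=int))
    rows = []
    for chrom, sub in frame.groupby("chrom", sort=False):
        pa = truth.pos_at_anc[hap][chrom]
        mapped = np.flatnonzero(pa >= 0)
        mapped_pos = pa[mapped]
        lo = np.searchsorted(mapped, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mapped, sub["end"].to_numpy(), side="left")
        for (_, row), l, h in zip(sub.iterrows(), lo.tolist(), hi.tolist()):
            if h <= l:
                continue  # interval fully deleted on this haplotype
            out = dict(row)
            out["start"] = int(mapped_pos[l])
            out["end"] = int(mapped_pos[h - 1]) + 1
            rows.append(out)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def _block_of(truth: TrioTruth, hap: str, chrom: str, pos0: np.ndarray, bs: int):
    """Ancestral block index of each haplotype position (forward-filled
    across inserted/alternate bases)."""
    anc = truth.anc_of[hap][chrom]
    anc_ff = np.maximum.accumulate(anc)
    return np.maximum(anc_ff[pos0], 0) // bs


def _parental_states(
    truth: TrioTruth,
    config: TrioConfig,
    hap: str,
    chrom: str,
    sites: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(sites)
    state = np.zeros(n, dtype=np.int8)
    ctx = sites["context"].to_numpy()
    if config.ancestral_block_states:
        bs = config.state_block_bp or 200
        blocks = _block_of(truth, hap, chrom, sites["pos0"].to_numpy(), bs)
        state = truth.block_states[chrom][blocks].astype(np.int8)
    elif config.state_block_bp:
        bs = config.state_block_bp
        n_blocks = config.chrom_length // bs + 2
        draws = rng.random((n_blocks, len(CONTEXTS)))
        blocks = _block_of(truth, hap, chrom, sites["pos0"].to_numpy(), bs)
        for k, c in enumerate(CONTEXTS):
            m = ctx == c
            state[m] = draws[blocks[m], k] < config.context_meth_prob[c]
    else:
        u = rng.random(n)
        for c in CONTEXTS:
            m = ctx == c
            state[m] = u[m] < config.context_meth_prob[c]

    # planted parental differential
    planted = truth.planted_blocks.get(chrom)
    if planted:
        target = {
            "cultivar": {"CF1": 1, "CF2": 1, "SB1": 0, "SB2": 0},
            "intra": {"CF1": 1, "CF2": 0, "SB1": 1, "SB2": 0},
        }[config.planted_diff_mode].get(hap)
        if target is not None:
            anc = truth.anc_of[hap][chrom]
            anc_ff = np.maximum.accumulate(anc)
            apos = np.maximum(anc_ff[sites["pos0"].to_numpy()], 0)
            in_planted = np.zeros(n, dtype=bool)
            for a0, a1 in planted:
                in_planted |= (apos >= a0) & (apos < a1)
            m = in_planted & (ctx == config.planted_diff_context)
            state[m] = target
    return state


def _apply_forced_genes(
    truth: TrioTruth, hap: str, chrom: str, sites: pd.DataFrame, state: np.ndarray
) -> None:
    if truth.gene_classes is None or hap not in truth.exons:
        return
    forced = truth.gene_classes.query("forced_class != 'none'")
    if forced.empty:
        return
    exons = truth.exons[hap]
    pos0 = sites["pos0"].to_numpy()
    ctx = sites["context"].to_numpy()
    for _, g in forced.iterrows():
        ex = exons[(exons["gene_id"] == g["gene_id"]) & (exons["chrom"] == chrom)]
        for _, e in ex.iterrows():
            m = (pos0 >= e["start"]) & (pos0 < e["end"])
            if g["forced_class"] == "gbM":
                state[m & (ctx == "CG")] = 1
                state[m & (ctx != "CG")] = 0
            else:  # teM
                state[m] = 1


def simulate_methylomes(
    truth: TrioTruth, config: TrioConfig
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-clone cytosine tables for every haplotype, plus state truth.

    Returns ``{haplotype: {clone: table}}`` with CX-style columns
    (chrom, pos 1-based, strand, count_m, count_u, context, trinuc).
    Clone names are shared between the two haplotypes of a cultivar.
    """
    rng_state = np.random.default_rng([config.seed, 31])
    rng_clone = np.random.default_rng([config.seed, 37])

    # planted differential blocks (chosen on the ancestral axis)
    if config.planted_diff_fraction > 0:
        bs = config.state_block_bp or 200
        for ci, chrom in enumerate(truth.chroms):
            prng = np.random.default_rng([config.seed, 41, ci])
            n_blocks = (config.chrom_length + bs - 1) // bs
            chosen = np.flatnonzero(prng.random(n_blocks) < config.planted_diff_fraction)
            truth.planted_blocks[chrom] = [
                (int(b) * bs, min((int(b) + 1) * bs, config.chrom_length))
                for b in chosen
            ]

    # parental states first, CS inherits
    site_frames: dict[str, list[pd.DataFrame]] = {h: [] for h in HAPLOTYPES}
    state_lookup: dict[tuple[str, str, str], dict] = {}
    for chrom in truth.chroms:
        for hap in PARENTAL_HAPLOTYPES:
            sites = cytosine_sites(truth.haplotype_sequences[hap][chrom])
            state = _parental_states(truth, config, hap, chrom, sites, rng_state)
            _apply_forced_genes(truth, hap, chrom, sites, state)
            sites = sites.assign(state=state)
            site_frames[hap].append(sites.assign(chrom=chrom))
            state_lookup[(hap, chrom, "seq")] = truth.haplotype_sequences[hap][chrom]
            state_lookup[(hap, chrom, "state")] = sites
        for cs_hap in ("CSCF", "CSSB"):
            sites = _inherit_states(
                truth, config, cs_hap, chrom, state_lookup, rng_state
            )
            site_frames[cs_hap].append(sites.assign(chrom=chrom))

    methylomes: dict[str, dict[str, pd.DataFrame]] = {}
    for hap in HAPLOTYPES:
        allsites = pd.concat(site_frames[hap], ignore_index=True)
        level = np.where(
            allsites["state"].to_numpy() > 0,
            config.level_methylated,
            config.level_unmethylated,
        )
        allsites = allsites.assign(level=level, pos=allsites["pos0"] + 1)
        truth.site_states[hap] = allsites[
            ["chrom", "pos", "strand", "context", "trinuc", "state", "level"]
        ].copy()

        cultivar = CULTIVAR_OF[hap]
        methylomes[hap] = {}
        n = len(allsites)
        for k in range(config.clones_per_cultivar):
            clone = f"{cultivar}_c{k + 1}"
            lvl = np.clip(
                level + rng_clone.normal(0.0, config.clone_noise_sd, size=n),
                0.0,
                100.0,
            )
            cov = rng_clone.poisson(config.mean_coverage, size=n)
            m = rng_clone.binomial(cov, lvl / 100.0)
            methylomes[hap][clone] = pd.DataFrame(
                {
                    "chrom": allsites["chrom"],
                    "pos": allsites["pos"],
                    "strand": allsites["strand"],
                    "count_m": m,
                    "count_u": cov - m,
                    "context": allsites["context"],
                    "trinuc": allsites["trinuc"],
                }
            )
    return methylomes


def _inherit_states(
    truth: TrioTruth,
    config: TrioConfig,
    cs_hap: str,
    chrom: str,
    state_lookup: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """CS sites copy the state of the inherited parental haplotype and
    flip with the epimutation probability."""
    seq = truth.haplotype_sequences[cs_hap][chrom]
    segments = truth.inheritance[chrom][cs_hap]
    sites = cytosine_sites(seq)
    n = len(sites)
    state = np.zeros(n, dtype=np.int8)

    if len(segments) == 1 and seq == state_lookup[(segments[0][2], chrom, "seq")]:
        # whole-haplotype inheritance: site tables are identical
        state[:] = state_lookup[(segments[0][2], chrom, "state")]["state"].to_numpy()
    else:
        pos0 = sites["pos0"].to_numpy()
        anc = truth.anc_of[cs_hap][chrom]
        apos = anc[pos0]
        filled = np.zeros(n, dtype=bool)
        for a0, a1, src in segments:
            src_sites = state_lookup[(src, chrom, "state")]
            src_state_by_key = {
                (int(p), s): int(st)
                for p, s, st in zip(
                    src_sites["pos0"], src_sites["strand"], src_sites["state"]
                )
            }
            pa = truth.pos_at_anc[src][chrom]
            in_seg = (apos >= a0) & (apos < a1)
            for i in np.flatnonzero(in_seg):
                sp = pa[apos[i]] if apos[i] >= 0 else -1
                key = (int(sp), sites["strand"].iat[i])
                if sp >= 0 and key in src_state_by_key:
                    state[i] = src_state_by_key[key]
                    filled[i] = True
        # sites with no homologous parental cytosine: draw fresh
        u = rng.random(n)
        ctx = sites["context"].to_numpy()
        for c in CONTEXTS:
            m = (~filled) & (ctx == c)
            state[m] = u[m] < config.context_meth_prob[c]

    flips = rng.random(n) < config.epimutation_rate
    state = np.where(flips, 1 - state, state).astype(np.int8)
    return sites.assign(state=state)


def simulate_trio(
    config: TrioConfig, annotations: bool = True, **ann_kwargs
) -> tuple[TrioTruth, dict[str, dict[str, pd.DataFrame]]]:
    """Full generator run: genomes + graph, annotations, methylomes."""
    truth = simulate_trio_genomes(config)
    if annotations:
        simulate_annotations(truth, config, **ann_kwargs)
    methylomes = simulate_methylomes(truth, config)
    return truth, methylomes


# ---------------------------------------------------------------------------
# single-reference bias emulation
# ---------------------------------------------------------------------------


def emit_single_reference_calls(
    truth: TrioTruth,
    sample_tables: dict[str, pd.DataFrame],
    sample_hap: str,
    reference_hap: str,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Emulate mapping a non-reference sample onto one linear reference.

    For every reference cytosine: sites at homologous positions keep the
    sample's counts; where the sample carries the C>T (G>A) transition of
    a reference cytosine, all reads are emitted as unmethylated; reference
    positions deleted or otherwise diverged in the sample are dropped.
    The result is indexed on reference coordinates.
    """
    for hap in (sample_hap, reference_hap):
        if hap not in HAPLOTYPES:
            raise KeyError(f"unknown haplotype {hap!r}")
    rng = np.random.default_rng([seed, 53])
    out: dict[str, list[pd.DataFrame]] = {c: [] for c in sample_tables}

    for chrom in truth.chroms:
        ref_seq = truth.haplotype_sequences[reference_hap][chrom]
        smp_seq = np.frombuffer(
            truth.haplotype_sequences[sample_hap][chrom].encode(), dtype=np.uint8
        )
        ref_sites = cytosine_sites(ref_seq)
        pos0 = ref_sites["pos0"].to_numpy()
        ref_to_sample = truth.hap_alignment(reference_hap, sample_hap, chrom)
        spos = ref_to_sample[pos0]
        valid = spos >= 0
        sbase = np.where(valid, smp_seq[np.maximum(spos, 0)], 0)
        is_plus = (ref_sites["strand"] == "+").to_numpy()
        ref_base = np.where(is_plus, _C, _G)
        same = valid & (sbase == ref_base)
        transition = valid & np.where(is_plus, sbase == _T, sbase == _A)

        for clone, table in sample_tables.items():
            sub = table[table["chrom"] == chrom]
            key = sub["pos"].to_numpy() * 2 + (sub["strand"] == "-").to_numpy()
            lut_m = dict(zip(key.tolist(), sub["count_m"].tolist()))
            lut_u = dict(zip(key.tolist(), sub["count_u"].tolist()))

            skey = (spos + 1) * 2 + (~is_plus).astype(np.int64)
            rows_m = np.zeros(len(ref_sites), dtype=np.int64)
            rows_u = np.zeros(len(ref_sites), dtype=np.int64)
            keep = np.zeros(len(ref_sites), dtype=bool)
            same_idx = np.flatnonzero(same)
            for i in same_idx.tolist():
                k = int(skey[i])
                if k in lut_m:
                    rows_m[i] = lut_m[k]
                    rows_u[i] = lut_u[k]
                    keep[i] = True
            tr_idx = np.flatnonzero(transition)
            rows_u[tr_idx] = rng.poisson(
                truth.config.mean_coverage, size=tr_idx.size
            )
            keep[tr_idx] = True

            res = ref_sites.loc[keep, ["pos0", "strand", "context", "trinuc"]].copy()
            res.insert(0, "chrom", chrom)
            res["pos"] = res.pop("pos0") + 1
            res["count_m"] = rows_m[keep]
            res["count_u"] = rows_u[keep]
            out[clone].append(
                res[["chrom", "pos", "strand", "count_m", "count_u", "context", "trinuc"]]
            )

    return {
        clone: pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["chrom", "pos", "strand", "count_m", "count_u", "context", "trinuc"]
        )
        for clone, frames in out.items()
    }


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_outputs(
    truth: TrioTruth,
    methylomes: dict[str, dict[str, pd.DataFrame]],
    outdir: str,
    biased: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write GFA, CX reports, GFF3/BED annotations and truth tables."""
    from .methio import write_cx_report
    from .genes import write_gff3, write_bed

    os.makedirs(outdir, exist_ok=True)
    truth.config.to_yaml(os.path.join(outdir, "config.yaml"))
    for chrom, graph in truth.graphs.items():
        write_gfa(graph, os.path.join(outdir, f"graph.{chrom}.gfa"))
    cxdir = os.path.join(outdir, "cx")
    os.makedirs(cxdir, exist_ok=True)
    for hap, clones in methylomes.items():
        for clone, table in clones.items():
            write_cx_report(
                table, os.path.join(cxdir, f"{hap}.{clone}.CX_report.txt")
            )
    if truth.genes:
        for hap in HAPLOTYPES:
            write_gff3(
                truth.genes.get(hap, pd.DataFrame()),
                truth.exons.get(hap, pd.DataFrame()),
                os.path.join(outdir, f"genes.{hap}.gff3"),
            )
            write_bed(
                truth.repeats.get(hap, pd.DataFrame()),
                os.path.join(outdir, f"repeats.{hap}.bed"),
            )
    tdir = os.path.join(outdir, "truth")
    os.makedirs(tdir, exist_ok=True)
    if truth.variants is not None:
        truth.variants.to_csv(os.path.join(tdir, "variants.tsv"), sep="\t", index=False)
    for hap, states in truth.site_states.items():
        states.to_csv(
            os.path.join(tdir, f"site_states.{hap}.tsv"), sep="\t", index=False
        )
    inh_rows = [
        {"chrom": c, "cs_hap": h, "anc_start": s, "anc_end": e, "source": src}
        for c, m in truth.inheritance.items()
        for h, segs in m.items()
        for s, e, src in segs
    ]
    pd.DataFrame(inh_rows).to_csv(
        os.path.join(tdir, "inheritance.tsv"), sep="\t", index=False
    )
    if truth.gene_classes is not None:
        truth.gene_classes.to_csv(
            os.path.join(tdir, "gene_classes.tsv"), sep="\t", index=False
        )
    if biased:
        bdir = os.path.join(outdir, "biased")
        os.makedirs(bdir, exist_ok=True)
        for clone, table in biased.items():
            write_cx_report(table, os.path.join(bdir, f"{clone}.CX_report.txt"))


# ---------------------------------------------------------------------------
# study scenarios
# ---------------------------------------------------------------------------


def null_scenario_config(seed: int, chrom_length: int = 450_000) -> TrioConfig:
    """No differential anywhere: every haplotype shares the same
    ancestral-block methylation states and the epimutation rate is zero."""
    return TrioConfig(
        chrom_length=chrom_length,
        seed=seed,
        epimutation_rate=0.0,
        ancestral_block_states=True,
        state_block_bp=200,
        context_meth_prob={"CG": 0.3, "CHG": 0.3, "CHH": 0.3},
    )


def inherited_differential_config(
    seed: int, chrom_length: int = 200_000, fraction: float = 0.1
) -> TrioConfig:
    """Parental CG differential planted in a fraction of 200 bp blocks
    (CF methylated, SB unmethylated); CS inherits one haplotype of each."""
    return TrioConfig(
        chrom_length=chrom_length,
        seed=seed,
        epimutation_rate=0.0,
        state_block_bp=200,
        planted_diff_fraction=fraction,
        planted_diff_context="CG",
        planted_diff_mode="cultivar",
    )


def intra_differential_config(
    seed: int, chrom_length: int = 200_000, fraction: float = 0.1
) -> TrioConfig:
    """Within-parent differential (hap1 methylated, hap2 unmethylated)
    for the intra-cultivar concordance analysis; epimutation off."""
    return TrioConfig(
        chrom_length=chrom_length,
        seed=seed,
        epimutation_rate=0.0,
        state_block_bp=200,
        planted_diff_fraction=fraction,
        planted_diff_context="CG",
        planted_diff_mode="intra",
    )


def refbias_scenario_config(seed: int, chrom_length: int = 100_000) -> TrioConfig:
    """Single-reference bias: block methylation states shared by all
    haplotypes, with C>T transitions planted on the SB lineage at 30% of
    the cytosines of methylated blocks."""
    return TrioConfig(
        chrom_length=chrom_length,
        seed=seed,
        epimutation_rate=0.0,
        ancestral_block_states=True,
        state_block_bp=200,
        ct_snp_fraction=0.3,
        context_meth_prob={"CG": 0.5, "CHG": 0.5, "CHH": 0.5},
    )
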