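"""Gene- and feature-level methylation.

Covers metagene profiles (100 bins per segment over upstream 1 kb, gene
body, downstream 1 kb), the gbM/teM gene classification from exonic
context means, DMR annotation against the gene/repeat space, structural
variant proximity, reciprocal allelic-pair detection through graph
projection, and the generic inherited-set intersection.

gbM (gene-body methylation): mean exonic CG level >= 20% with CHG and
CHH below 20%.  teM (TE-like methylation): mean >= 5% in all three
contexts and not gbM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .graph import SequenceGraph, project_position

__all__ = [
    "GeneModel",
    "genes_from_frames",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "metagene_profile",
    "classify_gene_methylation",
    "annotate_regions",
    "sv_proximity",
    "allelic_pairs",
    "inherited_sets",
]

PROMOTER_LEN = 3000  # bp upstream of the TSS


@dataclass
class GeneModel:
    """A gene with exons; coordinates 0-based half-open on one haplotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    meth_class: str = "unclassified"

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [
            (ex[i][1], ex[i + 1][0])
            for i in range(len(ex) - 1)
            if ex[i + 1][0] > ex[i][1]
        ]

    def promoter(self, length: int = PROMOTER_LEN) -> tuple[int, int]:
        """Region upstream of the TSS, clipped at the sequence start."""
        if self.strand == "-":
            return (self.end, self.end + length)
        return (max(0, self.start - length), self.start)


def genes_from_frames(
    genes_df: pd.DataFrame, exons_df: pd.DataFrame
) -> list[GeneModel]:
    by_gene = {g: [] for g in genes_df["gene_id"]}
    for _, e in exons_df.iterrows():
        if e["gene_id"] in by_gene:
            by_gene[e["gene_id"]].append((int(e["start"]), int(e["end"])))
    return [
        GeneModel(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            exons=sorted(by_gene.get(row["gene_id"], [])),
        )
        for _, row in genes_df.iterrows()
    ]


# ---------------------------------------------------------------------------
# annotation I/O (GFF3 1-based inclusive; BED 0-based half-open)
# ---------------------------------------------------------------------------


def write_gff3(genes_df: pd.DataFrame, exons_df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genes_df.empty:
            return
        for _, g in genes_df.iterrows():
            fh.write(
                f"{g['chrom']}\tpanmeth\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )
            ex = exons_df[exons_df["gene_id"] == g["gene_id"]]
            for k, (_, e) in enumerate(ex.iterrows(), start=1):
                fh.write(
                    f"{e['chrom']}\tpanmeth\texon\t{e['start'] + 1}\t{e['end']}\t.\t"
                    f"{g['strand']}\t.\tID={g['gene_id']}.exon{k};Parent={g['gene_id']}\n"
                )


def read_gff3(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            start0, end = int(f[3]) - 1, int(f[4])
            if f[2] == "gene":
                gid = attrs["ID"]
                genes[gid] = GeneModel(gid, f[0], start0, end, f[6])
            elif f[2] == "exon":
                parent = attrs.get("Parent")
                if parent in genes:
                    genes[parent].exons.append((start0, end))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


def write_bed(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write('track name="repeats"\n')
        for _, r in frame.iterrows():
            name = r.get("name", ".")
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{name}\n")


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[1]),
                    "end": int(f[2]),
                    "name": f[3] if len(f) > 3 else ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# metagene profile
# ---------------------------------------------------------------------------


def metagene_profile(
    genes: list[GeneModel],
    profile: pd.DataFrame,
    flank: int = 1000,
    bins: int = 100,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
) -> pd.DataFrame:
    """Mean methylation level in 3 x ``bins`` bins around gene loci.

    Bins 0..bins-1 cover the upstream flank (5' of the TSS, distal
    first), the next ``bins`` the gene body, the last ``bins`` the
    downstream flank — all strand-aware.  Site levels are averaged per
    bin within a gene, then across genes; empty bins stay missing.
    Genes shorter than ``bins`` bp simply use fractional bin widths.
    """
    sums = {c: np.zeros(3 * bins) for c in contexts}
    counts = {c: np.zeros(3 * bins) for c in contexts}
    by_chrom = {
        str(chrom): sub.sort_values("pos", kind="stable")
        for chrom, sub in profile.groupby("chrom", observed=True)
    }
    for gene in genes:
        sub = by_chrom.get(str(gene.chrom))
        if sub is None:
            continue
        pos0 = sub["pos"].to_numpy() - 1
        lo = np.searchsorted(pos0, gene.start - flank)
        hi = np.searchsorted(pos0, gene.end + flank)
        if hi <= lo:
            continue
        sites = sub.iloc[lo:hi]
        p = pos0[lo:hi]
        glen = gene.end - gene.start
        # segment-relative bin, 5'->3' on the gene strand
        before = p < gene.start
        inside = (p >= gene.start) & (p < gene.end)
        off_up = (p - (gene.start - flank)).clip(0, flank - 1)
        off_body = (p - gene.start).clip(0, max(glen - 1, 0))
        off_dn = (p - gene.end).clip(0, flank - 1)
        bin_up = (off_up * bins) // flank
        bin_body = (off_body * bins) // max(glen, 1)
        bin_dn = (off_dn * bins) // flank
        seg_bin = np.where(before, bin_up, np.where(inside, bins + bin_body, 2 * bins + bin_dn))
        if gene.strand == "-":
            seg_bin = 3 * bins - 1 - seg_bin
        levels = sites["level_mean"].to_numpy()
        ctx = sites["context"].to_numpy()
        for c in contexts:
            mask = ctx == c
            if not mask.any():
                continue
            gene_sum = np.bincount(seg_bin[mask], weights=levels[mask], minlength=3 * bins)
            gene_n = np.bincount(seg_bin[mask], minlength=3 * bins)
            filled = gene_n > 0
            sums[c][filled] += gene_sum[filled] / gene_n[filled]
            counts[c][filled] += 1
    rows = []
    for c in contexts:
        with np.errstate(invalid="ignore"):
            mean = np.where(counts[c] > 0, sums[c] / np.maximum(counts[c], 1), np.nan)
        segment = ["upstream"] * bins + ["body"] * bins + ["downstream"] * bins
        for b in range(3 * bins):
            rows.append(
                {
                    "context": c,
                    "bin": b,
                    "segment": segment[b],
                    "level": mean[b],
                    "n_genes": int(counts[c][b]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gbM / teM classification
# ---------------------------------------------------------------------------


def classify_gene_methylation(
    genes: list[GeneModel],
    profile: pd.DataFrame,
    gbm_threshold: float = 20.0,
    tem_threshold: float = 5.0,
) -> pd.DataFrame:
    """gbM/teM/other per gene from mean exonic levels per context.

    Genes lacking exonic sites in a required context are classed
    ``other`` and flagged.
    """
    by_chrom = {
        str(chrom): sub.sort_values("pos", kind="stable")
        for chrom, sub in profile.groupby("chrom", observed=True)
    }
    rows = []
    for gene in genes:
        sub = by_chrom.get(str(gene.chrom))
        means: dict[str, float] = {}
        if sub is not None:
            pos0 = sub["pos"].to_numpy() - 1
            pieces = []
            for s, e in gene.exons or [(gene.start, gene.end)]:
                lo, hi = np.searchsorted(pos0, (s, e))
                pieces.append(sub.iloc[lo:hi])
            exonic = pd.concat(pieces) if pieces else sub.iloc[0:0]
            for c in ("CG", "CHG", "CHH"):
                lv = exonic.loc[exonic["context"] == c, "level_mean"]
                if len(lv):
                    means[c] = float(lv.mean())
        missing = [c for c in ("CG", "CHG", "CHH") if c not in means]
        if missing:
            cls = "other"
        elif (
            means["CG"] >= gbm_threshold
            and means["CHG"] < gbm_threshold
            and means["CHH"] < gbm_threshold
        ):
            cls = "gbM"
        elif all(means[c] >= tem_threshold for c in ("CG", "CHG", "CHH")):
            cls = "teM"
        else:
            cls = "other"
        rows.append(
            {
                "gene_id": gene.gene_id,
                "mean_CG": means.get("CG", np.nan),
                "mean_CHG": means.get("CHG", np.nan),
                "mean_CHH": means.get("CHH", np.nan),
                "meth_class": cls,
                "missing_context": ",".join(missing),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DMR annotation and SV proximity
# ---------------------------------------------------------------------------

_PRIORITY = ("exon", "intron", "promoter", "repeat")


def annotate_regions(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    repeats: pd.DataFrame,
    promoter_len: int = PROMOTER_LEN,
) -> pd.DataFrame:
    """Label each region (columns chrom/start/end) by feature overlap
    with priority exon > intron > promoter > repeat > intergenic, plus a
    TE-overlap flag and the raw multi-overlap flags."""
    trees: dict[tuple[str, str], IntervalTree] = {}

    def _add(kind: str, chrom: str, s: int, e: int) -> None:
        if e > s:
            trees.setdefault((kind, str(chrom)), IntervalTree()).addi(s, e)

    for g in genes:
        for s, e in g.exons or [(g.start, g.end)]:
            _add("exon", g.chrom, s, e)
        for s, e in g.introns:
            _add("intron", g.chrom, s, e)
        ps, pe = g.promoter(promoter_len)
        _add("promoter", g.chrom, ps, pe)
    for _, r in repeats.iterrows():
        _add("repeat", r["chrom"], int(r["start"]), int(r["end"]))

    out = dmrs.copy()
    labels, te_flags, flags = [], [], {k: [] for k in _PRIORITY}
    for _, d in dmrs.iterrows():
        chrom, s, e = str(d["chrom"]), int(d["start"]), int(d["end"])
        hit = {
            kind: bool(trees.get((kind, chrom), IntervalTree()).overlap(s, e))
            for kind in _PRIORITY
        }
        label = next((k for k in _PRIORITY if hit[k]), "intergenic")
        labels.append(label)
        te_flags.append(hit["repeat"])
        for k in _PRIORITY:
            flags[k].append(hit[k])
    out["feature"] = labels
    out["te_overlap"] = te_flags
    for k in _PRIORITY:
        out[f"overlaps_{k}"] = flags[k]
    return out


def sv_proximity(
    dmrs: pd.DataFrame,
    svs: pd.DataFrame,
    maxgap: int = 1000,
    min_sv_len: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """DMR x structural-variant pairs within ``maxgap``.

    ``svs`` needs chrom/start/end (+ optional sv_type) on the same
    coordinates as the DMRs; variants shorter than ``min_sv_len`` are
    excluded.  Pairs overlap -> "within", otherwise "proximal".  Also
    returns a Fisher test of TE-containing DMRs vs impact by a large
    deletion (requires ``te_overlap`` in dmrs; skipped otherwise).
    """
    svs = svs[(svs["end"] - svs["start"]) >= min_sv_len].reset_index(drop=True)
    pairs = []
    impacted = np.zeros(len(dmrs), dtype=bool)
    for i, (_, d) in enumerate(dmrs.iterrows()):
        for _, v in svs[svs["chrom"] == d["chrom"]].iterrows():
            gap = max(v["start"] - d["end"], d["start"] - v["end"], 0)
            if v["start"] < d["end"] and v["end"] > d["start"]:
                cls = "within"
            elif gap <= maxgap:
                cls = "proximal"
            else:
                continue
            if cls == "within" and v.get("sv_type", "DEL") == "DEL":
                impacted[i] = True
            pairs.append(
                {
                    "dmr_index": i,
                    "sv_start": int(v["start"]),
                    "sv_end": int(v["end"]),
                    "distance_class": cls,
                    "gap": int(gap),
                }
            )
    test: dict = {"p_value": None, "odds_ratio": None}
    if "te_overlap" in dmrs.columns and len(dmrs):
        te = dmrs["te_overlap"].to_numpy(dtype=bool)
        tab = [
            [int((te & impacted).sum()), int((te & ~impacted).sum())],
            [int((~te & impacted).sum()), int((~te & ~impacted).sum())],
        ]
        if min(map(sum, tab)) > 0:
            oddsratio, p = stats.fisher_exact(tab)
            test = {"p_value": float(p), "odds_ratio": float(oddsratio), "table": tab}
    return pd.DataFrame(pairs), test


# ---------------------------------------------------------------------------
# allelic pairs and inherited sets
# ---------------------------------------------------------------------------


def allelic_pairs(
    graph: SequenceGraph,
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    path_a: str,
    path_b: str,
    min_overlap: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reciprocal allelic gene pairs between two haplotypes.

    Each gene's span is projected onto the other haplotype; a candidate
    match must overlap a native gene by >= ``min_overlap`` of the
    projected span, and pairs are kept only when detected in both
    directions.  Unpaired genes are categorized unprojectable /
    no_overlap / unidirectional.
    """

    def _best_match(gene: GeneModel, src: str, dst: str, natives: list[GeneModel]):
        a = project_position(graph, src, gene.start, dst)
        b = project_position(graph, src, gene.end - 1, dst)
        if a is None or b is None:
            return None, "unprojectable"
        lo, hi = (a, b + 1) if a <= b else (b, a + 1)
        span = hi - lo
        best, best_ov = None, 0
        for other in natives:
            ov = min(hi, other.end) - max(lo, other.start)
            if ov > best_ov:
                best, best_ov = other, ov
        if best is None or best_ov < min_overlap * span:
            return None, "no_overlap"
        return best.gene_id, None

    fwd: dict[str, str] = {}
    cat_a: dict[str, str] = {}
    for g in genes_a:
        match, reason = _best_match(g, path_a, path_b, genes_b)
        if match is None:
            cat_a[g.gene_id] = reason
        else:
            fwd[g.gene_id] = match
    rev: dict[str, str] = {}
    cat_b: dict[str, str] = {}
    for g in genes_b:
        match, reason = _best_match(g, path_b, path_a, genes_a)
        if match is None:
            cat_b[g.gene_id] = reason
        else:
            rev[g.gene_id] = match

    pairs = []
    for ga, gb in fwd.items():
        if rev.get(gb) == ga:
            pairs.append({"gene_a": ga, "gene_b": gb})
        else:
            cat_a[ga] = "unidirectional"
    paired_b = {p["gene_b"] for p in pairs}
    for gb, ga in rev.items():
        if gb not in paired_b:
            cat_b[gb] = "unidirectional"

    unpaired = [
        {"gene_id": gid, "haplotype": hap, "category": cat}
        for hap, cats in ((path_a, cat_a), (path_b, cat_b))
        for gid, cat in cats.items()
    ]
    return (
        pd.DataFrame(pairs, columns=["gene_a", "gene_b"]),
        pd.DataFrame(unpaired, columns=["gene_id", "haplotype", "category"]),
    )


def inherited_sets(set_a: pd.DataFrame, set_b: pd.DataFrame) -> pd.DataFrame:
    """Ids significant in both input sets with the same sign.

    Inputs need columns ``id`` and ``sign`` (+1/-1).  Disjoint id
    universes yield an empty frame (with a warning).
    """
    merged = set_a.merge(set_b, on="id", suffixes=("_a", "_b"))
    if merged.empty and len(set_a) and len(set_b):
        import warnings

        warnings.warn("inherited_sets: no shared ids between the two sets")
    same = merged[merged["sign_a"] == merged["sign_b"]]
    return same.rename(columns={"sign_a": "sign"})[["id", "sign"]].reset_index(
        drop=True
    )
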