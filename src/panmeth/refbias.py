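"""Single-linear-reference bias: quantification and correction.

Mapping every sample onto one linear reference hides genome-specific
cytosines and converts sample-side C>T substitutions into apparently
unmethylated calls.  The correction ports methylation from the sample's
own haplotype through homologous 200 bp chunks defined on the graph
(the graph already encodes the haplotype alignment, so chunk pairing
uses path projection with the same 150-250 bp / unambiguous-mapping
rules as the DMA windows).  Regions are grouped by the pre/post
correction contrast (corrected / original / low delta / high delta at
the 75% level and 20-point delta thresholds) and the substitution
spectrum of each group is tested for C>T (G>A) enrichment with Fisher's
exact test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .graph import PathInterval, PathVariant, SequenceGraph, project_interval, project_position

__all__ = [
    "homologous_chunks",
    "port_methylation",
    "classify_correction_groups",
    "substitution_enrichment",
]


def homologous_chunks(
    graph: SequenceGraph,
    ref_path: str,
    alt_path: str,
    size: int = 200,
    min_len: int = 150,
    max_len: int = 250,
) -> list[tuple[PathInterval, PathInterval]]:
    """Tile the reference path into chunks and pair each with its
    projection on the alternative path.

    Chunks with an ambiguous or missing projection, or whose projected
    length falls outside [min_len, max_len], are dropped.
    """
    pairs = []
    L = graph.path_length(ref_path)
    for start in range(0, L, size):
        end = min(start + size, L)
        if end - start < min_len:
            continue
        ref_iv = PathInterval(ref_path, start, end)
        alt_iv = project_interval(graph, ref_iv, alt_path)
        if alt_iv is None:
            continue
        if not (min_len <= alt_iv.length <= max_len):
            continue
        pairs.append((ref_iv, alt_iv))
    return pairs


def _pooled_site_levels(tables: dict[str, pd.DataFrame], chrom: str | None):
    """Pool clone counts per site -> (pos0, context, level%) frame."""
    frames = []
    for table in tables.values():
        sub = table if chrom is None else table[table["chrom"] == chrom]
        frames.append(sub[["pos", "strand", "context", "count_m", "count_u"]])
    allc = pd.concat(frames, ignore_index=True)
    pooled = allc.groupby(["pos", "strand", "context"], as_index=False, sort=True).sum()
    cov = pooled["count_m"] + pooled["count_u"]
    pooled = pooled[cov > 0].reset_index(drop=True)
    pooled["level"] = 100.0 * pooled["count_m"] / (pooled["count_m"] + pooled["count_u"])
    pooled["pos0"] = pooled["pos"] - 1
    return pooled


def port_methylation(
    biased_tables: dict[str, pd.DataFrame],
    sample_tables: dict[str, pd.DataFrame],
    chunks: list[tuple[PathInterval, PathInterval]],
    graph: SequenceGraph | None = None,
    chrom: str | None = None,
    contexts: tuple[str, ...] = ("all", "CG", "CHG", "CHH"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace single-reference calls with the sample's own calls in each
    homologous chunk.

    ``biased_tables`` hold the sample's single-reference calls on
    reference coordinates, ``sample_tables`` its unbiased calls on its
    own haplotype.  Returns (records, ported_sites): per-chunk mean
    levels before/after correction (per context and overall), and the
    per-site transfer with reference coordinates where the site
    projects through the graph.  Chunks with no sites on either side are
    excluded.
    """
    ref_sites = _pooled_site_levels(biased_tables, chrom)
    alt_sites = _pooled_site_levels(sample_tables, chrom)
    ref_pos = ref_sites["pos0"].to_numpy()
    alt_pos = alt_sites["pos0"].to_numpy()

    records = []
    ported_rows = []
    for ref_iv, alt_iv in chunks:
        pre_lo, pre_hi = np.searchsorted(ref_pos, (ref_iv.start, ref_iv.end))
        post_lo, post_hi = np.searchsorted(alt_pos, (alt_iv.start, alt_iv.end))
        pre = ref_sites.iloc[pre_lo:pre_hi]
        post = alt_sites.iloc[post_lo:post_hi]
        if pre.empty and post.empty:
            continue
        chunk_id = f"{ref_iv.path_name}:{ref_iv.start}-{ref_iv.end}"
        for context in contexts:
            pre_c = pre if context == "all" else pre[pre["context"] == context]
            post_c = post if context == "all" else post[post["context"] == context]
            if pre_c.empty and post_c.empty:
                continue
            records.append(
                {
                    "chunk_id": chunk_id,
                    "ref_start": ref_iv.start,
                    "ref_end": ref_iv.end,
                    "alt_start": alt_iv.start,
                    "alt_end": alt_iv.end,
                    "context": context,
                    "pre": float(pre_c["level"].mean()) if len(pre_c) else np.nan,
                    "post": float(post_c["level"].mean()) if len(post_c) else np.nan,
                    "n_pre": len(pre_c),
                    "n_post": len(post_c),
                }
            )
        if graph is not None:
            for _, site in post.iterrows():
                rp = project_position(
                    graph, alt_iv.path_name, int(site["pos0"]), ref_iv.path_name
                )
                ported_rows.append(
                    {
                        "chunk_id": chunk_id,
                        "alt_pos0": int(site["pos0"]),
                        "ref_pos0": rp if rp is not None else -1,
                        "strand": site["strand"],
                        "context": site["context"],
                        "level": site["level"],
                    }
                )
    rec = pd.DataFrame(records)
    if not rec.empty:
        rec["delta"] = (rec["post"] - rec["pre"]).abs()
    return rec, pd.DataFrame(ported_rows)


def classify_correction_groups(
    records: pd.DataFrame, high_level: float = 75.0, delta_min: float = 20.0
) -> pd.DataFrame:
    """Exclusive region groups from the pre/post contrast.

    corrected: >= high_level only post-correction with delta >= delta_min;
    original: >= high_level only pre-correction with delta >= delta_min;
    otherwise low_delta (delta < delta_min) or high_delta.
    """
    out = records.copy()
    pre = out["pre"].fillna(0.0).to_numpy()
    post = out["post"].fillna(0.0).to_numpy()
    delta = np.abs(post - pre)
    out["delta"] = delta
    big = delta >= delta_min
    corrected = big & (post >= high_level) & (pre < high_level)
    original = big & (pre >= high_level) & (post < high_level)
    group = np.where(
        corrected,
        "corrected",
        np.where(
            original,
            "original",
            np.where(big, "high_delta", "low_delta"),
        ),
    )
    out["group"] = group
    return out


_SUB_TYPES = [f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b]


def substitution_enrichment(
    grouped_records: pd.DataFrame,
    variants: list[PathVariant],
    focus_group: str = "corrected",
) -> tuple[pd.DataFrame, dict]:
    """SNP substitution spectrum per correction group plus a Fisher test
    of the C>T (and G>A) fraction in ``focus_group`` vs all others.

    Variant positions (``pos_a`` on the reference path) are assigned to
    chunks by interval overlap; only SNPs enter the spectrum.  With no
    SNPs in the focus group the test is skipped (p = None).
    """
    regions = grouped_records[grouped_records["context"] == "all"] if (
        "context" in grouped_records.columns
        and (grouped_records["context"] == "all").any()
    ) else grouped_records
    snps = [v for v in variants if v.type == "SNP"]
    starts = regions["ref_start"].to_numpy()
    ends = regions["ref_end"].to_numpy()
    order = np.argsort(starts)
    counts: dict[str, dict[str, int]] = {}
    groups = regions["group"].to_numpy()
    for v in snps:
        i = np.searchsorted(starts[order], v.pos_a, side="right") - 1
        if i < 0:
            continue
        ridx = order[i]
        if not (starts[ridx] <= v.pos_a < ends[ridx]):
            continue
        sub = f"{v.allele_a}>{v.allele_b}"
        g = groups[ridx]
        counts.setdefault(g, {t: 0 for t in _SUB_TYPES})
        if sub in counts[g]:
            counts[g][sub] += 1
    spectrum = pd.DataFrame(
        [
            {"group": g, "substitution": s, "n": n}
            for g, subs in counts.items()
            for s, n in subs.items()
        ]
    )
    focus = counts.get(focus_group, {t: 0 for t in _SUB_TYPES})
    others = {t: 0 for t in _SUB_TYPES}
    for g, subs in counts.items():
        if g == focus_group:
            continue
        for t, n in subs.items():
            others[t] += n
    ct = ("C>T", "G>A")
    a = sum(focus[t] for t in ct)
    b = sum(n for t, n in focus.items() if t not in ct)
    c = sum(others[t] for t in ct)
    d = sum(n for t, n in others.items() if t not in ct)
    if a + b == 0:
        test = {"odds_ratio": None, "p_value": None, "table": ((a, b), (c, d))}
    else:
        oddsratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        test = {"odds_ratio": float(oddsratio), "p_value": float(p), "table": ((a, b), (c, d))}
    return spectrum, test
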