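"""Cytosine report I/O, coverage filtering and clone uniting.

Tables follow the bismark CX-report layout: chromosome, 1-based
position, strand, methylated count, unmethylated count, context
(CG/CHG/CHH) and trinucleotide.  A united profile holds, per haplotype,
the sites common to all clones of a cultivar with per-clone counts kept
separate (clones are biological replicates and enter the differential
test as samples, so their counts are never averaged here).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "read_cx_report",
    "write_cx_report",
    "filter_by_coverage",
    "unite_clones",
    "united_profiles",
    "site_methylated",
    "clone_names",
    "level_matrix",
]

CX_COLUMNS = ["chrom", "pos", "strand", "count_m", "count_u", "context", "trinuc"]


def context_of_trinuc(trinuc: str) -> str:
    """Sequence context of a 5'->3' trinucleotide starting at the cytosine."""
    if len(trinuc) < 2 or trinuc[1] == "G":
        return "CG"
    if len(trinuc) < 3 or trinuc[2] == "G":
        return "CHG"
    return "CHH"


def read_cx_report(path) -> pd.DataFrame:
    """Read a 7-column CX report; the context column is cross-checked
    against the trinucleotide and a mismatch raises ``ValueError``."""
    table = pd.read_csv(
        path,
        sep="\t",
        names=CX_COLUMNS,
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "count_m": np.int64,
            "count_u": np.int64,
            "context": str,
            "trinuc": str,
        },
    )
    expected = table["trinuc"].map(context_of_trinuc)
    bad = table.index[expected != table["context"]]
    if len(bad):
        row = table.loc[bad[0]]
        raise ValueError(
            f"context/trinucleotide mismatch at {row['chrom']}:{row['pos']} "
            f"({row['context']} vs trinucleotide {row['trinuc']})"
        )
    if (table[["count_m", "count_u"]].to_numpy() < 0).any():
        raise ValueError("negative counts in CX report")
    return table


def write_cx_report(table: pd.DataFrame, path) -> None:
    table[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def filter_by_coverage(table: pd.DataFrame, min_cov: int = 10) -> pd.DataFrame:
    """Keep sites with total coverage >= ``min_cov`` (lo.count rule)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    cov = table["count_m"] + table["count_u"]
    return table[cov >= min_cov].reset_index(drop=True)


def unite_clones(
    tables: dict[str, pd.DataFrame], destrand: bool = False
) -> pd.DataFrame:
    """Intersect per-clone tables on (chrom, pos, strand).

    Returns a wide profile with per-clone ``m_<clone>``/``u_<clone>``
    columns plus the across-clone mean methylation level.  With
    ``destrand=True`` the two strands of a symmetric CpG are pooled onto
    the plus-strand position before intersecting (disabled by default:
    strands are kept separate).
    """
    if len(tables) < 2:
        raise ValueError("need at least two clone tables to unite")
    keys = ["chrom", "pos", "strand"]
    merged: pd.DataFrame | None = None
    for clone, table in tables.items():
        t = table
        if destrand:
            t = _destrand(t)
        t = t[keys + ["context", "count_m", "count_u"]].rename(
            columns={"count_m": f"m_{clone}", "count_u": f"u_{clone}"}
        )
        if merged is None:
            merged = t
        else:
            merged = merged.merge(
                t.drop(columns="context"), on=keys, how="inner", sort=False
            )
    assert merged is not None
    if merged.empty:
        warnings.warn("united profile is empty: clones share no sites")
    merged = merged.sort_values(keys, kind="stable").reset_index(drop=True)
    clones = clone_names(merged)
    levels = level_matrix(merged, clones)
    merged["level_mean"] = levels.mean(axis=1)
    return merged


def _destrand(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    minus_cg = (t["context"] == "CG") & (t["strand"] == "-")
    t.loc[minus_cg, "pos"] -= 1
    t.loc[minus_cg, "strand"] = "+"
    grouped = (
        t.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=False)
        .agg({"count_m": "sum", "count_u": "sum", "trinuc": "first"})
    )
    return grouped


def united_profiles(
    methylomes: dict[str, dict[str, pd.DataFrame]],
    min_cov: int = 10,
    destrand: bool = False,
) -> dict[str, pd.DataFrame]:
    """Coverage-filter and unite every haplotype's clone tables."""
    return {
        hap: unite_clones(
            {c: filter_by_coverage(t, min_cov) for c, t in clones.items()},
            destrand=destrand,
        )
        for hap, clones in methylomes.items()
    }


def clone_names(profile: pd.DataFrame) -> list[str]:
    return [c[2:] for c in profile.columns if c.startswith("m_")]


def level_matrix(profile: pd.DataFrame, clones: list[str] | None = None) -> np.ndarray:
    """Per-clone methylation level (%) matrix, sites x clones."""
    clones = clones or clone_names(profile)
    m = profile[[f"m_{c}" for c in clones]].to_numpy(dtype=float)
    u = profile[[f"u_{c}" for c in clones]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * m / (m + u)


def site_methylated(level, threshold: float = 20.0):
    """Methylated-site rule: level >= threshold (inclusive boundary)."""
    return np.asarray(level) >= threshold
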